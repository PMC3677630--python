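"""Declarative builders for the hippocampal network variants.

Five variants share a common plan: object input (LEC) and context input (MEC)
feed a posterior (object-dominated) and an anterior (context-dominated)
hippocampal side, each with its own DG, CA3, and a distal/proximal pair of
CA1 subregions driving one output stream each:

=======  =========  =============  ==============  ================
output   side       CA1 subregion  upstream CA3    upstream DG blade
=======  =========  =============  ==============  ================
O        posterior  distal         proximal        inferior
OBCG     posterior  proximal       distal          superior
CBOG     anterior   distal         proximal        inferior
C        anterior   proximal       distal          superior
=======  =========  =============  ==============  ================

* ``Baseline`` -- one DG and one CA3 per side.
* ``SplitDG`` -- DG split into superior/inferior blades (half size each)
  receiving different crossconnection strengths; CA3 stays unified.
* ``AllSplit`` -- DG blades plus a split CA3 (proximal/distal); the inferior
  blade projects only to proximal CA3 and the superior blade only to distal
  CA3.
* ``SplitDGplus`` / ``AllSplitplus`` -- same wiring as their base variant but
  with the split DG (and, for AllSplitplus, CA3) layers doubled in size, to
  equalize training-set error with the Baseline.

Crossconnections (MEC into the posterior side, LEC into the anterior side)
carry per-region relative weight multipliers; mossy fibers (DG->CA3) are 10x
stronger than the perforant-path inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

from .netcore import LayerSpec, NetworkSpec, ProjectionSpec

__all__ = [
    "VARIANTS",
    "ArchitectureConfig",
    "STREAM_MAP",
    "default_config",
    "build_network",
    "validate_spec",
    "describe",
]

VARIANTS = ("Baseline", "SplitDG", "AllSplit", "SplitDGplus", "AllSplitplus")

# output -> (side, CA1 subregion, upstream CA3 region, upstream DG blade)
STREAM_MAP: dict[str, tuple[str, str, str, str]] = {
    "O": ("posterior", "distal", "proximal", "inferior"),
    "OBCG": ("posterior", "proximal", "distal", "superior"),
    "CBOG": ("anterior", "distal", "proximal", "inferior"),
    "C": ("anterior", "proximal", "distal", "superior"),
}

# activity fractions (fraction of units active under kWTA inhibition)
ACTIVITY = {"EC": 0.25, "DG": 0.015, "CA3": 0.023, "CA1": 0.025, "OUT": 0.25}

# multiplier used for "crossconnection strength close to zero" in split
# variants: kept slightly positive so the projection exists and can be swept
NEAR_ZERO_MULTIPLIER = 0.05


@dataclass(frozen=True)
class ArchitectureConfig:
    """Sizes and relative-weight multipliers for one network variant."""

    variant: str
    ec_size: int = 64
    dg_size: int = 800          # per side; split variants use dg_size/2 per blade
    ca3_size: int = 256         # per side; AllSplit uses ca3_size/2 per region
    posterior_ca3_size: int | None = None  # override for the posterior side only
    ca1_size: int = 400         # per CA1 subregion (two per side)
    output_size: int = 64
    objects_per_context: int = 3  # CBOG layer is this many object patterns wide
    size_multiplier: int = 1      # doubling factor for the "+" variants' split layers
    # posterior-side MEC crossconnection multipliers, per receiving region
    posterior_cross: Mapping[str, float] = field(default_factory=dict)
    # single shared anterior-side LEC crossconnection multiplier; set by the
    # calibration sweep (argmin of the C/CBOG sample-task average lies at 0,
    # kept slightly positive so the projections exist and can be swept)
    anterior_cross: float = NEAR_ZERO_MULTIPLIER
    mossy_multiplier: float = 10.0
    primary_multiplier: float = 1.0
    recurrent_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        for nm in ("ec_size", "dg_size", "ca3_size", "ca1_size", "output_size"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be positive")
        for region, mult in self.posterior_cross.items():
            if mult < 0:
                raise ValueError(f"negative multiplier for {region!r}")

    @property
    def split_dg(self) -> bool:
        return self.variant != "Baseline"

    @property
    def split_ca3(self) -> bool:
        return self.variant in ("AllSplit", "AllSplitplus")

    @property
    def blade_size(self) -> int:
        return (self.dg_size // 2) * self.size_multiplier

    def side_ca3_size(self, side: str) -> int:
        if side == "posterior" and self.posterior_ca3_size is not None:
            return self.posterior_ca3_size
        return self.ca3_size

    def ca3_region_size(self, side: str = "posterior") -> int:
        size = self.side_ca3_size(side)
        if not self.split_ca3:
            return size
        return (size // 2) * self.size_multiplier

    @property
    def cbog_size(self) -> int:
        return self.output_size * self.objects_per_context


def _baseline_cross() -> dict[str, float]:
    return {"DG": 1.5, "CA3": 1.5, "CA1proximal": 1.5}


def _split_cross(split_ca3: bool) -> dict[str, float]:
    # the O stream (inferior blade / proximal CA3) takes strong context input;
    # the OBCG stream takes a multiplier close to 0
    cross = {
        "DGinferior": 3.0,
        "DGsuperior": NEAR_ZERO_MULTIPLIER,
        "CA1proximal": NEAR_ZERO_MULTIPLIER,
    }
    if split_ca3:
        cross["CA3proximal"] = 3.0
        cross["CA3distal"] = NEAR_ZERO_MULTIPLIER
    else:
        cross["CA3"] = 1.5  # unsplit CA3 shared by both streams keeps the compromise
    return cross


def default_config(variant: str) -> ArchitectureConfig:
    """The published sizes and crossconnection multipliers for one variant."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if variant == "Baseline":
        cross = _baseline_cross()
    else:
        cross = _split_cross(split_ca3=variant in ("AllSplit", "AllSplitplus"))
    size_multiplier = 2 if variant.endswith("plus") else 1
    return ArchitectureConfig(
        variant=variant,
        posterior_cross=cross,
        size_multiplier=size_multiplier,
    )


def _posterior_mult(cfg: ArchitectureConfig, region: str) -> float:
    try:
        return cfg.posterior_cross[region]
    except KeyError:
        raise ValueError(
            f"variant {cfg.variant!r}: no posterior crossconnection multiplier for {region!r}"
        ) from None


def build_network(cfg: ArchitectureConfig) -> NetworkSpec:
    """Emit the layer/projection spec implementing the configured variant."""
    layers: list[LayerSpec] = [
        LayerSpec("LEC", cfg.ec_size, ACTIVITY["EC"], clampable=True),
        LayerSpec("MEC", cfg.ec_size, ACTIVITY["EC"], clampable=True),
    ]
    projections: list[ProjectionSpec] = []

    for side, prefix in (("posterior", "p"), ("anterior", "a")):
        # primary input comes in at full strength; the other EC division is the
        # crossconnection, scaled per receiving region
        primary = "LEC" if side == "posterior" else "MEC"
        cross = "MEC" if side == "posterior" else "LEC"

        def cross_mult(region: str) -> float:
            if side == "posterior":
                return _posterior_mult(cfg, region)
            return cfg.anterior_cross

        # --- DG ---
        if cfg.split_dg:
            dg_layers = {
                "superior": f"{prefix}DGsup",
                "inferior": f"{prefix}DGinf",
            }
            for blade, name in dg_layers.items():
                layers.append(LayerSpec(name, cfg.blade_size, ACTIVITY["DG"]))
                projections.append(ProjectionSpec(primary, name, cfg.primary_multiplier))
                projections.append(ProjectionSpec(cross, name, cross_mult(f"DG{blade}")))
        else:
            dg = f"{prefix}DG"
            layers.append(LayerSpec(dg, cfg.dg_size, ACTIVITY["DG"]))
            projections.append(ProjectionSpec(primary, dg, cfg.primary_multiplier))
            projections.append(ProjectionSpec(cross, dg, cross_mult("DG")))

        # --- CA3 ---
        if cfg.split_ca3:
            ca3_layers = {
                "proximal": f"{prefix}CA3prox",
                "distal": f"{prefix}CA3dist",
            }
            for region, name in ca3_layers.items():
                layers.append(LayerSpec(name, cfg.ca3_region_size(side), ACTIVITY["CA3"]))
                projections.append(ProjectionSpec(primary, name, cfg.primary_multiplier))
                projections.append(ProjectionSpec(cross, name, cross_mult(f"CA3{region}")))
                projections.append(ProjectionSpec(name, name, cfg.recurrent_multiplier))
            # inferior blade -> proximal CA3 only; superior blade -> distal only
            projections.append(
                ProjectionSpec(dg_layers["inferior"], ca3_layers["proximal"], cfg.mossy_multiplier)
            )
            projections.append(
                ProjectionSpec(dg_layers["superior"], ca3_layers["distal"], cfg.mossy_multiplier)
            )
        else:
            ca3 = f"{prefix}CA3"
            layers.append(LayerSpec(ca3, cfg.side_ca3_size(side), ACTIVITY["CA3"]))
            projections.append(ProjectionSpec(primary, ca3, cfg.primary_multiplier))
            projections.append(ProjectionSpec(cross, ca3, cross_mult("CA3")))
            projections.append(ProjectionSpec(ca3, ca3, cfg.recurrent_multiplier))
            if cfg.split_dg:
                for name in dg_layers.values():
                    projections.append(ProjectionSpec(name, ca3, cfg.mossy_multiplier))
            else:
                projections.append(ProjectionSpec(dg, ca3, cfg.mossy_multiplier))

        # --- CA1 and outputs ---
        ca1_distal = f"{prefix}CA1d"
        ca1_proximal = f"{prefix}CA1p"
        layers.append(LayerSpec(ca1_distal, cfg.ca1_size, ACTIVITY["CA1"]))
        layers.append(LayerSpec(ca1_proximal, cfg.ca1_size, ACTIVITY["CA1"]))
        # CA3 proximal -> CA1 distal, CA3 distal -> CA1 proximal
        if cfg.split_ca3:
            projections.append(ProjectionSpec(ca3_layers["proximal"], ca1_distal, 1.0))
            projections.append(ProjectionSpec(ca3_layers["distal"], ca1_proximal, 1.0))
        else:
            projections.append(ProjectionSpec(ca3, ca1_distal, 1.0))
            projections.append(ProjectionSpec(ca3, ca1_proximal, 1.0))
        # distal CA1 receives LEC, proximal CA1 receives MEC
        lec_mult = cfg.primary_multiplier if side == "posterior" else cfg.anterior_cross
        mec_mult = cross_mult("CA1proximal") if side == "posterior" else cfg.primary_multiplier
        projections.append(ProjectionSpec("LEC", ca1_distal, lec_mult))
        projections.append(ProjectionSpec("MEC", ca1_proximal, mec_mult))

        # output layers, bidirectional so plus-phase targets reach CA1
        distal_out = "O" if side == "posterior" else "CBOG"
        proximal_out = "OBCG" if side == "posterior" else "C"
        distal_size = cfg.cbog_size if distal_out == "CBOG" else cfg.output_size
        layers.append(LayerSpec(distal_out, distal_size, ACTIVITY["OUT"], clampable=True))
        layers.append(LayerSpec(proximal_out, cfg.output_size, ACTIVITY["OUT"], clampable=True))
        projections.append(ProjectionSpec(ca1_distal, distal_out, 1.0, bidirectional=True))
        projections.append(ProjectionSpec(ca1_proximal, proximal_out, 1.0, bidirectional=True))

    return NetworkSpec(name=cfg.variant, layers=tuple(layers), projections=tuple(projections))


def _expected_layer_names(cfg: ArchitectureConfig) -> set[str]:
    names = {"LEC", "MEC", "O", "OBCG", "CBOG", "C"}
    for prefix in ("p", "a"):
        names |= {f"{prefix}CA1d", f"{prefix}CA1p"}
        names |= (
            {f"{prefix}DGsup", f"{prefix}DGinf"} if cfg.split_dg else {f"{prefix}DG"}
        )
        names |= (
            {f"{prefix}CA3prox", f"{prefix}CA3dist"} if cfg.split_ca3 else {f"{prefix}CA3"}
        )
    return names


def validate_spec(spec: NetworkSpec, cfg: ArchitectureConfig | None = None) -> list[str]:
    """Audit a spec against the variant's wiring rules; return violations."""
    if cfg is None:
        cfg = default_config(spec.name) if spec.name in VARIANTS else None
    violations: list[str] = []
    names = set(spec.layer_names)
    edges = {(p.source, p.target) for p in spec.projections}

    if cfg is not None:
        expected = _expected_layer_names(cfg)
        for extra in sorted(names - expected):
            violations.append(f"unexpected layer {extra!r}")
        for missing in sorted(expected - names):
            violations.append(f"missing layer {missing!r}")
        sizes = {
            "LEC": cfg.ec_size,
            "MEC": cfg.ec_size,
            "O": cfg.output_size,
            "OBCG": cfg.output_size,
            "C": cfg.output_size,
            "CBOG": cfg.cbog_size,
        }
        for name, size in sizes.items():
            if name in names and spec.layer(name).size != size:
                violations.append(f"layer {name!r} has size {spec.layer(name).size}, expected {size}")

    # each output stream is wired to exactly one CA1 subregion, per the map
    ca1_of = {"O": "pCA1d", "OBCG": "pCA1p", "CBOG": "aCA1d", "C": "aCA1p"}
    for out, ca1 in ca1_of.items():
        if out not in names:
            continue
        feeders = {src for (src, tgt) in edges if tgt == out}
        if feeders != {ca1}:
            violations.append(f"output {out!r} fed by {sorted(feeders)}, expected [{ca1!r}]")

    # blade -> CA3 wiring in fully split variants
    for prefix in ("p", "a"):
        if f"{prefix}CA3prox" in names and f"{prefix}DGsup" in names:
            if (f"{prefix}DGsup", f"{prefix}CA3prox") in edges:
                violations.append(f"superior blade must not project to {prefix}CA3prox")
            if (f"{prefix}DGinf", f"{prefix}CA3dist") in edges:
                violations.append(f"inferior blade must not project to {prefix}CA3dist")
            if (f"{prefix}DGinf", f"{prefix}CA3prox") not in edges:
                violations.append(f"missing mossy projection {prefix}DGinf->{prefix}CA3prox")
            if (f"{prefix}DGsup", f"{prefix}CA3dist") not in edges:
                violations.append(f"missing mossy projection {prefix}DGsup->{prefix}CA3dist")

    return violations


def describe(spec: NetworkSpec):
    """Layer and projection tables as DataFrames (for auditing/CSV export)."""
    import pandas as pd

    layer_rows = [
        {
            "layer": l.name,
            "size": l.size,
            "activity_fraction": l.activity_fraction,
            "k_active": l.k_active,
            "clampable": l.clampable,
        }
        for l in spec.layers
    ]
    proj_rows = [
        {
            "source": p.source,
            "target": p.target,
            "rel_weight": p.rel_weight,
            "learnable": p.learnable,
            "bidirectional": p.bidirectional,
        }
        for p in spec.projections
    ]
    return pd.DataFrame(layer_rows), pd.DataFrame(proj_rows)
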