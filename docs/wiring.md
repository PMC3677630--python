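# Wiring audit

Anatomical justification for every projection class emitted by the
architecture builders.  `hippoctx describe --variant <V>` prints the concrete
per-variant projection table (source, target, relative weight, learnability,
directionality); this table explains why each class of projection exists.

| projection class | variants | rel. weight | anatomical basis |
|---|---|---|---|
| LEC → posterior DG/CA3 | all | 1.0 | perforant-path input; LEC (object stream) is the posterior side's primary input |
| MEC → posterior DG/CA3 | all | crossconnection table (1.5 Baseline; 3.0 O-stream / 0.05 OBCG-stream in split variants) | caudolateral MEC band also reaches the posterior half; strength is the central experimental variable |
| MEC → anterior DG/CA3 | all | 1.0 | MEC (context stream) is the anterior side's primary input |
| LEC → anterior DG/CA3 | all | shared anterior multiplier (0.05, from the calibration sweep) | rostromedial LEC band reaches the anterior half; single shared strength for all variants |
| DG → CA3 (mossy fibers) | all | 10.0 | mossy fibers are sparse but very strong; modeled as a dense projection with 10x relative weight |
| DG inferior blade → proximal CA3 only; superior blade → distal CA3 only | AllSplit, AllSplitplus | 10.0 | blade-specific mossy targeting (modeling simplification: the superior blade's projection to proximal CA3 is omitted) |
| CA3 → CA3 (recurrent) | all | 1.0 | recurrent collaterals supporting pattern completion; no inter-region CA3 connections in split variants |
| CA3 proximal → CA1 distal, CA3 distal → CA1 proximal | all | 1.0 | crossed Schaffer topography of the distal/proximal axes |
| LEC → CA1 distal, MEC → CA1 proximal | all | 1.0 primary side; crossconnection table otherwise | temporoammonic input: LEC targets distal CA1, MEC proximal CA1 |
| CA1 ↔ output | all | 1.0, bidirectional | CA1 is the output stage (via subiculum/EC V-VI, not modeled explicitly); the feedback direction carries plus-phase target information for learning |

Blade-strength asymmetry (thicker lateral-perforant-path lamina on the
superior blade, thicker medial on the inferior) is realized solely through
the crossconnection multiplier table: the inferior (O-stream) blade takes the
strong MEC multiplier and the superior (OBCG-stream) blade the near-zero one
on the posterior side.
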