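# TNM 8th-edition staging tables for lung cancer (T size buckets, node size
# cutoff, nodal station -> N map).  Thresholds are inclusive upper bounds in
# millimeters ("<= 30 mm" is T1c); a null threshold is the open top bucket.
# Swap this file to move to another edition without code changes.
version: tnm8

t_size_thresholds_mm:
  - [10, T1a]
  - [20, T1b]
  - [30, T1c]
  - [40, T2a]
  - [50, T2b]
  - [70, T3]
  - [null, T4]

# Feature classes (from invasion_target concepts) and structural cues mapped
# to the minimum T they impose; the final T is the max of size-T and feature-T.
feature_to_t:
  T2: T2
  T3: T3
  T4: T4
  satellite_same_lobe: T3
  separate_nodule_other_lobe: T4

# Short-axis cutoff for calling a node enlarged on CT.
node_size_cutoff_mm: 10

# Station -> N stage, by relation of the node side to the tumor side.
# Station 1 (supraclavicular/scalene) is N3 regardless of side; station 7
# (subcarinal) is N2 regardless of side.
station_to_n:
  1:  {ipsilateral: N3, contralateral: N3}
  2:  {ipsilateral: N2, contralateral: N3}
  3:  {ipsilateral: N2, contralateral: N3}
  4:  {ipsilateral: N2, contralateral: N3}
  5:  {ipsilateral: N2, contralateral: N3}
  6:  {ipsilateral: N2, contralateral: N3}
  7:  {ipsilateral: N2, contralateral: N2}
  8:  {ipsilateral: N2, contralateral: N3}
  9:  {ipsilateral: N2, contralateral: N3}
  10: {ipsilateral: N1, contralateral: N3}
  11: {ipsilateral: N1, contralateral: N3}
  12: {ipsilateral: N1, contralateral: N3}
  13: {ipsilateral: N1, contralateral: N3}
  14: {ipsilateral: N1, contralateral: N3}

# Fallback when a pathologic node has no recognizable station: map its
# regional wording instead (graceful degradation, with a trace warning).
region_to_n:
  mediastinal: N2
  hilar: N1
  supraclavicular: N3
  unknown: N2
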