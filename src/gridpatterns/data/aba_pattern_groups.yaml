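# Example region-group configuration for re-runs on the Allen developing
# mouse brain atlas energy table.  The pattern-index lists reference the 45
# ranked recurrent patterns of the published atlas analysis; the coordinate
# ranges are overridable defaults (the exact published ranges are not
# machine-readable).
grid:
  n_ap: 20
  n_dv: 4
  discrepancy_interfaces: [[[1, 1], [1, 2]], [[8, 1], [8, 2]]]
groups:
  forebrain:
    ap: [1, 6]
    patterns: [3, 4, 6, 8, 10, 11, 16, 18, 27, 31, 32, 34, 36, 37, 38]
  hindbrain:
    ap: [9, 20]
    patterns: [1, 2, 5, 7, 9, 13, 14, 15, 17, 19, 20, 21, 22, 24, 26, 30, 35, 43, 45]
  dorsal:
    dv: [1, 2]
    patterns: [5, 11, 14, 19, 27, 32, 34]
  ventral:
    dv: [3, 4]
    patterns: [10, 13, 16, 17, 18, 20, 21, 24, 26, 30, 31, 35, 39]
  control: {}
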