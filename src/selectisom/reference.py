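"""Published benchmark numbers for the cathepsin K/S selectivity panel.

The original 153-compound panel is not deposited, but its printed summary
tables are, and their arithmetic is reproducible exactly: per-cluster
composition counts with purity percentages for the bonded-atom-pair (BAPS)
and MACCS maps, the overall BAPS performance row, and reference selectivity
ratios. These serve as fixed inputs for validating the purity, performance
and set-assignment arithmetic of this package. The combined-fingerprint
table of the same benchmark is internally inconsistent (row totals disagree
with the member counts) and is deliberately not included.
"""

from __future__ import annotations

# Per-cluster counts (K/S, KS, S/K) and the printed purity percent.
# BAPS map: 26 clusters, all rows arithmetically consistent.
BAPS_CLUSTER_TABLE: list[tuple[int, int, int, int, int]] = [
    # (K/S, KS, S/K, printed purity %, printed total)
    (2, 15, 10, 56, 27),
    (2, 11, 3, 69, 16),
    (15, 0, 0, 100, 15),
    (11, 0, 1, 92, 12),
    (0, 6, 5, 55, 11),
    (0, 0, 8, 100, 8),
    (6, 1, 0, 86, 7),
    (0, 4, 2, 67, 6),
    (0, 5, 0, 100, 5),
    (4, 0, 0, 100, 4),
    (0, 0, 4, 100, 4),
    (0, 0, 4, 100, 4),
    (0, 0, 4, 100, 4),
    (0, 0, 3, 100, 3),
    (1, 1, 0, 50, 2),
    (2, 0, 0, 100, 2),
    (0, 0, 2, 100, 2),
    (0, 0, 2, 100, 2),
    (0, 0, 2, 100, 2),
    (1, 0, 0, 100, 1),
    (0, 1, 0, 100, 1),
    (1, 0, 0, 100, 1),
    (0, 0, 1, 100, 1),
    (0, 0, 1, 100, 1),
    (1, 0, 0, 100, 1),
    (0, 0, 1, 100, 1),
]

# MACCS map: only the first 20 rows are arithmetically consistent; the
# remaining printed rows contradict their own totals and are omitted.
MACCS_CLUSTER_TABLE_HEAD: list[tuple[int, int, int, int, int]] = [
    (2, 9, 28, 72, 39),
    (28, 2, 0, 93, 30),
    (0, 1, 10, 91, 11),
    (0, 10, 1, 91, 11),
    (0, 7, 0, 100, 7),
    (6, 0, 0, 100, 6),
    (0, 1, 5, 83, 6),
    (0, 0, 4, 100, 4),
    (4, 0, 0, 100, 4),
    (0, 0, 4, 100, 4),
    (0, 3, 0, 100, 3),
    (0, 0, 3, 100, 3),
    (0, 3, 0, 100, 3),
    (0, 2, 0, 100, 2),
    (2, 0, 0, 100, 2),
    (0, 2, 0, 100, 2),
    (1, 1, 0, 50, 2),
    (0, 2, 0, 100, 2),
    (0, 2, 0, 100, 2),
    (0, 1, 0, 100, 1),
]

#: printed overall BAPS performance row: (error %, coverage %, correct %)
BAPS_PERFORMANCE_ROW = (18, 94, 76)

#: benchmark library size
LIBRARY_SIZE = 153

#: reference selectivity ratios quoted for the panel, with favored target
#: and the set label they were assigned under the 50-fold convention
REFERENCE_SRS: list[tuple[float, str, str]] = [
    (235_000.0, "K", "K/S"),
    (1099.0, "K", "K/S"),
    (8.8, "K", "KS"),
    (9.4, "S", "KS"),
    (34_483.0, "S", "S/K"),
    (1000.0, "S", "S/K"),
]

#: selectivity ratios reported for the five externally validated screening
#: hits, with their favored target where selective
VALIDATED_HIT_SRS: list[tuple[float, str]] = [
    (300.0, "K"),
    (890.0, "K"),
    (25.0, "S"),
    (5.0, "K"),
    (1.5, "S"),
]
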