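"""Published reference values used for validation.

These tables come from a published staged-drought RNA-seq study of
perennial ryegrass (leaf and root tissue sampled at 35, 15, 5 and 1
percent estimated water content) whose analysis this package re-implements.
They are consumed as plain inputs: the contingency counts feed the Fisher
primitive, and the per-contrast J1/J3 counts feed the jury bookkeeping, so
that the pipeline's arithmetic can be checked against printed results.
"""

from __future__ import annotations

#: Mirror-image enzyme-code comparisons: (tissue, scheme, category_1,
#: category_2, ec, k1, n1, k2, n2, printed_p).  ``printed_p`` is None where
#: the source prints only an upper bound of 1e-4.  Two further published
#: rows are omitted because their printed p-values are inconsistent with
#: their own printed counts under any test laterality.
MIRROR_EC_REFERENCE = [
    ("shoot", "AR", "up_up_up", "down_down_down", "EC:3.1.3.16", 5, 105, 1, 166, 3.39e-2),
    ("shoot", "AR", "ns_up_ns", "ns_down_ns", "EC:3.6.1.15", 3, 319, 26, 404, None),
    ("shoot", "AR", "ns_up_ns", "ns_down_ns", "EC:3.6.1.3", 1, 319, 15, 404, 1.50e-3),
    ("shoot", "AR", "ns_ns_up", "ns_ns_down", "EC:1.11.1.7", 4, 1139, 21, 1276, 1.89e-3),
    ("shoot", "AR", "ns_ns_up", "ns_ns_down", "EC:3.6.1.15", 17, 1139, 50, 1276, 2.70e-4),
    ("shoot", "AR", "ns_ns_up", "ns_ns_down", "EC:3.6.1.3", 12, 1139, 35, 1276, 2.87e-3),
    ("shoot", "TC", "ns_up_down", "ns_down_up", "EC:3.6.1.15", 2, 178, 12, 228, 2.73e-2),
    ("shoot", "TC", "ns_up_down", "ns_down_up", "EC:3.6.1.3", 0, 178, 10, 228, 3.08e-3),
    ("shoot", "TC", "ns_up_ns", "ns_down_ns", "EC:3.6.1.15", 4, 423, 18, 518, 1.51e-2),
    ("root", "AR", "ns_up", "ns_down", "EC:1.11.1.7", 3, 314, 21, 528, 9.68e-3),
    ("root", "AR", "ns_up_up", "ns_down_down", "EC:1.11.1.7", 1, 156, 12, 330, 7.05e-2),
    ("root", "AR", "ns_up_up", "ns_down_down", "EC:4.1.1.2", 0, 156, 18, 330, 1.25e-3),
    ("root", "AR", "ns_ns_up", "ns_ns_down", "EC:1.11.1.7", 9, 1805, 44, 1761, None),
    ("root", "AR", "ns_ns_up", "ns_ns_down", "EC:3.6.1.15", 39, 1805, 86, 1761, None),
    ("root", "AR", "ns_ns_up", "ns_ns_down", "EC:3.6.1.3", 33, 1805, 63, 1761, 1.28e-3),
    ("root", "TC", "ns_ns_up", "ns_ns_down", "EC:3.1.3.16", 18, 1274, 9, 1625, 1.93e-2),
    ("root", "TC", "ns_ns_up", "ns_ns_down", "EC:1.11.1.7", 6, 1274, 45, 1625, None),
    ("root", "TC", "ns_ns_up", "ns_ns_down", "EC:3.6.1.15", 28, 1274, 87, 1625, None),
    ("root", "TC", "ns_ns_up", "ns_ns_down", "EC:3.6.1.3", 21, 1274, 65, 1625, 1.60e-4),
]

#: Published per-contrast (J1, J3) significant-gene counts.
J1_J3_REFERENCE = {
    "leaf": {
        "AR/TC Early": (1050, 642),
        "AR Middle": (1838, 1195),
        "TC Middle": (1860, 1290),
        "AR Late": (3762, 3024),
        "TC Late": (2701, 2065),
    },
    "root": {
        "AR/TC Early": (5, 0),
        "AR Middle": (844, 0),
        "TC Middle": (186, 1),
        "AR Late": (3932, 2903),
        "TC Late": (2757, 1787),
    },
}
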