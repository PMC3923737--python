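"""Published filtering-table constants used by the arithmetic tests.

Per length: (total reads, total %, [(class reads, class %), ...]) with class
columns ordered rRNA, tRNA, snRNA, snoRNA, cpRNA, mtRNA, all-filters. The
23-nt mtRNA percentage is printed as 0.02 in the source table but
2,279/1,335,058 = 0.17%; that single inconsistent cell is excluded from the
exact-arithmetic assertions.
"""

GRAND_TOTAL = 13_953_403
RETAINED_AFTER_FILTERS = 12_597_985

TABLE2 = {
    18: (369_493, 2.65, [(132_827, 35.95), (9_763, 2.64), (283, 0.08),
                         (167, 0.05), (6_069, 1.64), (2_269, 0.61),
                         (151_378, 40.97)]),
    19: (445_999, 3.20, [(131_575, 29.50), (22_091, 4.95), (241, 0.05),
                         (130, 0.03), (10_314, 2.31), (2_043, 0.46),
                         (166_394, 37.31)]),
    20: (503_781, 3.61, [(107_113, 21.26), (14_525, 2.88), (240, 0.05),
                         (102, 0.02), (27_221, 5.40), (2_534, 0.50),
                         (151_735, 30.12)]),
    21: (2_869_361, 20.56, [(164_287, 5.73), (5_755, 0.20), (959, 0.03),
                            (78, 0.00), (51_618, 1.80), (14_261, 0.50),
                            (236_958, 8.26)]),
    22: (2_271_978, 16.28, [(117_565, 5.17), (7_860, 0.35), (374, 0.02),
                            (61, 0.00), (106_135, 4.67), (3_714, 0.16),
                            (235_709, 10.37)]),
    23: (1_335_058, 9.57, [(125_303, 9.39), (7_860, 0.59), (257, 0.02),
                           (33, 0.00), (23_003, 1.72), (2_279, None),
                           (158_735, 11.89)]),
    24: (5_760_030, 41.28, [(102_477, 1.78), (9_347, 0.16), (356, 0.01),
                            (27, 0.00), (31_370, 0.54), (3_447, 0.06),
                            (147_024, 2.55)]),
    25: (397_703, 2.85, [(87_646, 22.04), (6_541, 1.64), (178, 0.04),
                         (17, 0.00), (8_911, 2.24), (4_192, 1.05),
                         (107_485, 27.03)]),
    "Total": (13_953_403, 100.00, [(968_793, 6.94), (83_742, 0.60),
                                   (2_888, 0.02), (615, 0.00),
                                   (264_641, 1.90), (34_739, 0.25),
                                   (1_355_418, 9.71)]),
}

CLASS_ORDER = ("rRNA", "tRNA", "snRNA", "snoRNA", "cpRNA", "mtRNA")


def seq_of(index: int, length: int) -> str:
    """Deterministic distinct ACGU sequence of a given length."""
    bases = "ACGU"
    out = []
    i = index
    for _ in range(length):
        out.append(bases[i % 4])
        i //= 4
    return "".join(out)


def table2_classified_tags():
    """ClassifiedTag objects whose per-length/per-class read totals reproduce
    the published table (one synthetic tag per cell plus an unclassified
    remainder tag per length)."""
    from seedmir.ncrna import ClassifiedTag
    from seedmir.preprocess import SmallReadTag

    out = []
    i = 0
    for length, (total, _, cells) in TABLE2.items():
        if length == "Total":
            continue
        all_filters = cells[-1][0]
        for cname, (count, _) in zip(CLASS_ORDER, cells[:-1]):
            out.append(ClassifiedTag(SmallReadTag(seq_of(i, length), count), cname))
            i += 1
        out.append(ClassifiedTag(
            SmallReadTag(seq_of(i, length), total - all_filters), "none"))
        i += 1
    return out
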