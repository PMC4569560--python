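"""Independent brute-force oracles shared by the test modules."""


def forced_count_oracle(tc_counts, pmn_counts):
    """Pure-python availability bookkeeping for forced P=1 bonding between
    directly opposing planar faces.

    Two species loops (outer over PMN species mirrors the implementation's
    bond-type ordering for a single TC species); each TC molecule bonds while
    its opposing partner face still holds a whole molecule of the current
    species.
    """
    tc = [float(c) for c in tc_counts[:, 0]]
    pmn = pmn_counts.astype(float).copy()
    total = 0
    for s in range(pmn.shape[1]):
        for i in range(len(tc)):
            while tc[i] >= 1.0 and pmn[i, s] >= 1.0:
                tc[i] -= 1.0
                pmn[i, s] -= 1.0
                total += 1
    return total
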