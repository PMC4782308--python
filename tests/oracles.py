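"""Independent reference implementations used only to check the package."""


def brute_force_cluster(records, cutoff):
    """Literal 'take the global max, remove its neighborhood, repeat'
    clustering, written without any of the package's clustering code.

    records: list of (reference, strand, position, rrs).
    Returns a list of clusters, each a (peak, members) pair with members
    given as the original tuples, and clusters reported in peak-selection
    order.
    """
    remaining = list(records)
    clusters = []
    while remaining:
        # global max RRS; ties to the leftmost position, then ref/strand order
        peak = min(remaining, key=lambda r: (-r[3], r[0], r[1], r[2]))
        members = [
            r for r in remaining
            if r[0] == peak[0] and r[1] == peak[1] and abs(r[2] - peak[2]) <= cutoff
        ]
        for m in members:
            remaining.remove(m)
        clusters.append((peak, members))
    return clusters
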