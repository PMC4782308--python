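import pysam
import pytest

from capseq import (
    SimConfig,
    call_tss,
    cluster_tss,
    compute_rrs,
    depleted_sites,
    extract_five_prime_ends,
    read_alignments,
    simulate,
)


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """One full default simulation plus the called/clustered results,
    shared across the suite (the simulation itself is deterministic)."""
    out = tmp_path_factory.mktemp("default_sim")
    config = SimConfig(seed=1)
    genome, genes, truth = simulate(config, out)
    cap = extract_five_prime_ends(read_alignments(out / "cap.sam"), "cap")
    control = extract_five_prime_ends(read_alignments(out / "control.sam"), "control")
    compute_rrs(cap)
    compute_rrs(control)
    candidates = call_tss(cap, control)
    clustered = cluster_tss(candidates, 5)
    depleted = depleted_sites(cap, control)
    return {
        "dir": out,
        "config": config,
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "cap": cap,
        "control": control,
        "candidates": candidates,
        "clustered": clustered,
        "depleted": depleted,
    }


def make_sam(path, reads, reference="chr", length=10_000):
    """Write a SAM file from (name, flag, pos0, cigar, seq, mapq, tags) tuples."""
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": reference, "LN": length}]}
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for name, flag, pos0, cigar, seq, mapq, tags in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = name
            a.flag = flag
            a.reference_id = 0 if not (flag & 4) else -1
            a.reference_start = pos0
            a.mapping_quality = mapq
            a.cigarstring = cigar
            a.query_sequence = seq
            for tag, val in tags:
                a.set_tag(tag, val)
            out.write(a)
    return path
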