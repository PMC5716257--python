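import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def write_sam(path, sq_lengths, records):
    """Write a minimal SAM file.

    ``records`` are (qname, flag, rname, pos1, cigar, seq, tags) tuples;
    tags is a list of raw tag strings like "MD:Z:75".
    """
    with open(path, "w") as out:
        out.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, length in sq_lengths.items():
            out.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for qname, flag, rname, pos1, cigar, seq, tags in records:
            qual = "I" * len(seq) if seq != "*" else "*"
            fields = [
                qname, str(flag), rname, str(pos1), "60", cigar,
                "*", "0", "0", seq, qual,
            ] + list(tags)
            out.write("\t".join(fields) + "\n")
    return path


@pytest.fixture
def sam_writer():
    return write_sam


@pytest.fixture(scope="session")
def hybrid_run(tmp_path_factory):
    """The standard simulated-hybrid study: one 1 Mbp chromosome, parents
    diverged at 10% per base, 8 syntenic blocks of 50-70 kbp of which 3 are
    introgressed, reads at 15x depth with truth alignments to the maternal
    reference."""
    from introscan.simulate import (
        generate_toy_parents,
        make_simulated_hybrids,
        pairs_for_depth,
        simulate_reads,
    )

    out = tmp_path_factory.mktemp("hybrid_run")
    toy = generate_toy_parents(
        out,
        n_chrom=1,
        chrom_length=1_000_000,
        divergence_rate=0.10,
        n_blocks=8,
        block_length_range=(50_000, 70_000),
        seed=11,
    )
    hybrid_fa, log = make_simulated_hybrids(
        toy.maternal_fasta,
        toy.paternal_fasta,
        toy.blocks,
        seed=11,
        n_select=3,
        out_fasta=out / "hybrid.fasta",
    )
    reads = simulate_reads(
        hybrid_fa,
        n_pairs=pairs_for_depth(15.0, 1_000_000),
        seed=11,
        out_prefix=out / "reads",
    )
    selected = {
        (b.maternal_chrom, b.maternal_start) for b in log.selected_blocks
    }
    negatives = [
        b.maternal_region()
        for b in toy.blocks
        if (b.maternal_chrom, b.maternal_start) not in selected
    ]
    return {
        "dir": out,
        "toy": toy,
        "hybrid_fasta": hybrid_fa,
        "log": log,
        "reads": reads,
        "truths": log.truth_regions,
        "negatives": negatives,
    }


@pytest.fixture(scope="session")
def hybrid_detect(hybrid_run):
    """Full-coverage detection on the standard simulated hybrid at the
    tuned operating point (w = 1 kbp, frac = 0.05, t = 0.90)."""
    from introscan.harness import detect_from_placements

    return detect_from_placements(
        hybrid_run["reads"].placements,
        hybrid_run["toy"].maternal_fasta,
        hybrid_run["truths"],
        hybrid_run["negatives"],
        hybrid_run["dir"] / "detect",
        window=1000,
        frac=0.05,
        threshold=0.90,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
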