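import pytest

import supersage as ss


@pytest.fixture(scope="session")
def noise_free_sim(tmp_path_factory):
    """A small noise-free simulated experiment shared across tests.

    All error channels are off and every tag is 26 bp, so the simulator's
    expected-count bookkeeping is an exact oracle for extraction.
    """
    cfg = ss.SimulationConfig(
        n_transcripts=300, length_range=(100, 400),
        depth_lib1=5000, depth_lib2=5000,
        de_fraction=0.1, de_fold=8.0,
        substitution_error_rate=0.0, n_rate=0.0,
        low_quality_read_fraction=0.0,
        tag_len_probs={26: 1.0}, seed=3)
    outdir = tmp_path_factory.mktemp("sim")
    transcripts = ss.generate_transcriptome(cfg)
    truth = ss.assign_expression(transcripts, cfg)
    result = ss.simulate_reads(transcripts, truth, cfg,
                               outdir / "lib1.fastq", outdir / "lib2.fastq")
    fasta = ss.write_transcriptome(transcripts, outdir / "transcriptome.fasta")
    return {
        "config": cfg, "transcripts": transcripts, "truth": truth,
        "result": result, "fasta": fasta, "outdir": outdir,
    }


def write_fastq(path, records):
    """records: iterable of (id, seq, qual) triples."""
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    return path
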