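import pytest

from chimeraloci.synthdata import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def synth_dir(tmp_path_factory):
    """A zero-jitter synthetic study shared across tests."""
    outdir = tmp_path_factory.mktemp("synth")
    manifest = generate_dataset(SynthConfig(seed=11), outdir)
    return outdir, manifest


@pytest.fixture(scope="session")
def pipeline_run(synth_dir, tmp_path_factory):
    """A completed pipeline run on the shared synthetic study."""
    from chimeraloci.pipeline import GenomeInput, RunConfig, run_pipeline

    outdir, manifest = synth_dir
    run_dir = tmp_path_factory.mktemp("run")
    cfg = RunConfig(
        transcripts_fasta=str(outdir / "transcripts.fasta"),
        self_hits=str(outdir / "self_hits.tsv"),
        protein_hits=str(outdir / "protein_hits.tsv"),
        contam_hits=str(outdir / "contam_hits.tsv"),
        counts=str(outdir / "counts.tsv"),
        totals=str(outdir / "totals.tsv"),
        genomes=[
            GenomeInput(g, str(outdir / f"genome_hits.{g}.tsv"), str(outdir / "genomes" / f"{g}.gff3"))
            for g in manifest["genomes"]
        ],
        outdir=str(run_dir),
    )
    report = run_pipeline(cfg)
    return run_dir, manifest, report
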