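import pytest

from capricirc import synthetic
from capricirc.genome import AnnotatedGenome, Exon, Gene
from capricirc.junctions import call_backsplice_junctions, classify_all, detect_split_reads
from capricirc.report import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def scenario():
    """The default seeded synthetic scenario, shared across the suite."""
    return synthetic.default_scenario(seed=0)


@pytest.fixture(scope="session")
def called(scenario):
    """Detection + calling run once on the shared scenario."""
    chim = {}
    libs = {}
    for sample, reads in scenario.sim.reads.items():
        det = detect_split_reads(reads, scenario.genome, 20, sample=sample)
        chim[sample] = det.chimeras
        libs[sample] = det.n_mapped
    records, rejected = call_backsplice_junctions(chim, scenario.genome)
    classify_all(records, scenario.genome)
    return records, rejected, libs


@pytest.fixture(scope="session")
def pipeline_report(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("pipe")
    cfg = RunConfig(outdir=str(outdir), seed=0)
    return run_pipeline(cfg), outdir


@pytest.fixture()
def toy_genome():
    """Hand-built two-gene genome with exact, known coordinates.

    chr1 layout (+ gene gA): exons [100,200) [400,500) [700,800) [1000,1100),
    introns carry GT..AG.  gB on - strand further downstream.
    """
    import numpy as np

    rng = np.random.default_rng(123)
    seq = list("".join(rng.choice(list("ACGT"), size=5000)))
    gA = Gene("gA", "chr1", "+", [Exon(100, 200), Exon(400, 500), Exon(700, 800), Exon(1000, 1100)])
    gB = Gene("gB", "chr1", "-", [Exon(2000, 2150), Exon(2400, 2550), Exon(2800, 2950)])
    genome = AnnotatedGenome({"chr1": "".join(seq)}, [gA, gB])
    for g in genome.genes:
        for istart, iend in g.introns:
            if g.strand == "+":
                genome.patch("chr1", istart, "GT")
                genome.patch("chr1", iend - 2, "AG")
            else:
                genome.patch("chr1", istart, "CT")
                genome.patch("chr1", iend - 2, "AC")
    return genome
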