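import warnings
from types import SimpleNamespace

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def neutral_mutator():
    """Codon-sequence mutator that is neutral per NG86 site class.

    Each site mutates with the given rate, choosing uniformly among the
    three alternatives; a mutation that would create a stop codon is
    redirected to another nonsynonymous non-stop alternative at the same
    site (dropped if none exists), so realized synonymous/nonsynonymous
    substitution probabilities stay proportional to the site counts.
    """
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for s in table.stop_codons:
        code[s] = "*"

    def mutate(seq: str, rate: float, rng):
        b = list(seq)
        for i in range(len(b)):
            if rng.random() >= rate:
                continue
            start = 3 * (i // 3)
            codon = "".join(b[start : start + 3])
            aa = code[codon]
            pos = i - start
            alt = str(rng.choice([x for x in "ACGT" if x != b[i]]))
            mut = codon[:pos] + alt + codon[pos + 1 :]
            if code[mut] == "*":
                others = [
                    codon[:pos] + x + codon[pos + 1 :]
                    for x in "ACGT"
                    if x not in (codon[pos], alt)
                ]
                options = [m for m in others if code[m] not in ("*", aa)]
                if not options:
                    continue
                mut = str(rng.choice(options))
            b[start : start + 3] = list(mut)
        return "".join(b)

    return mutate


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One mid-size simulated dataset pushed through the ribo-seq stages.

    Shared across alignment/feature/classifier tests; everything is seeded
    so the bundle is deterministic.
    """
    from ribocall.alignment import load_alignments
    from ribocall.annotation import assign_biotypes
    from ribocall.pipeline import label_catalog, run_ribo_stages
    from ribocall.simulate import (
        SimConfig,
        simulate_footprints,
        simulate_rnaseq,
        simulate_transcriptome,
        write_sam,
    )

    cfg = SimConfig(seed=11, n_mrna=60, n_lncrna=30, n_short_ncrna=10)
    sim = simulate_transcriptome(cfg)
    d = tmp_path_factory.mktemp("demo")
    write_sam(simulate_footprints(sim), sim.genome, d / "ribo.sam")
    write_sam(simulate_rnaseq(sim), sim.genome, d / "rna.sam")
    reads = load_alignments(d / "ribo.sam")
    run = run_ribo_stages(reads, sim.transcripts, sim.genome)
    biotypes = assign_biotypes(
        sim.transcripts, coding=[t for t in sim.transcripts if t.has_cds]
    )
    labels = label_catalog(run.features, sim.truth.translated_keys)
    return SimpleNamespace(
        cfg=cfg,
        sim=sim,
        reads=reads,
        run=run,
        biotypes=biotypes,
        labels=labels,
        ribo_sam=d / "ribo.sam",
        rna_sam=d / "rna.sam",
    )


@pytest.fixture(scope="session")
def demo_model(demo_run):
    """SVM trained on the shared dataset with the paper-style pools."""
    from ribocall.classifier import (
        FEATURE_COLUMNS,
        TrainingSpec,
        TranslatedOrfSVM,
        build_sets,
    )

    spec = TrainingSpec(
        n_pos_train=30, n_neg_train=60, n_pos_test=30, n_neg_test=60, seed=11
    )
    train, test = build_sets(demo_run.run.features, spec, demo_run.biotypes)
    model = TranslatedOrfSVM(random_state=11).fit(
        train[list(FEATURE_COLUMNS)].to_numpy(), train["label"].to_numpy()
    )
    return SimpleNamespace(model=model, spec=spec, train=train, test=test)
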