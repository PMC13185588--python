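"""Shared fixtures: heavier simulated runs are session-scoped so the unit
tests and the acceptance-property tests reuse the same computations."""

import numpy as np
import pandas as pd
import pytest

from plaquetx.compare import convergence_analysis, label_genes
from plaquetx.dge import run_contrasts
from plaquetx.pipeline import run_all
from plaquetx.simulate import (SimDesign, generate_catalog, generate_counts,
                               make_convergent_truth)


@pytest.fixture(scope="session")
def small_catalog():
    d = SimDesign(n_species=4, genes_per_species=8, n_kos=8, seed=101,
                  shared_block_fraction=0.25)
    return d, generate_catalog(d)


@pytest.fixture(scope="session")
def null_run():
    """Pure-null paired simulation: 2,000 features, 12 + 7 subjects,
    dispersion 0.1, with the fitted DGE table."""
    d = SimDesign(n_species=20, genes_per_species=100,
                  frac_shared_de=0.0, frac_groupA_de=0.0,
                  frac_groupB_de=0.0, frac_opposite_de=0.0,
                  dispersion=0.1, baseline_mean=200.0, seed=11)
    cat = generate_catalog(d)
    counts, sheet, truth = generate_counts(d, cat)
    table = run_contrasts(counts, sheet)
    return {"design": d, "counts": counts, "sheet": sheet,
            "truth": truth, "dge": table}


@pytest.fixture(scope="session")
def planted_run():
    """Default planted design (|lfc| 1.5, baseline 200, dispersion 0.1) on
    1,000 features, with DGE table and labels."""
    d = SimDesign(n_species=20, genes_per_species=50, seed=5)
    cat = generate_catalog(d)
    counts, sheet, truth = generate_counts(d, cat)
    table = run_contrasts(counts, sheet)
    labels = label_genes(table)
    return {"design": d, "counts": counts, "sheet": sheet,
            "truth": truth.loc[labels.index], "dge": table, "labels": labels}


@pytest.fixture(scope="session")
def convergence_run():
    """40-KO catalog with 12 planted convergent and 6 identical-attribution
    KOs, run through DGE, labeling and convergence analysis."""
    d = SimDesign(n_species=10, genes_per_species=80, n_kos=40, seed=21)
    cat = generate_catalog(d)
    truth = make_convergent_truth(d, cat, n_convergent_kos=12, n_identical_kos=6)
    planted = set(truth.attrs["convergent_kos"])
    identical = set(truth.attrs["identical_kos"])
    counts, sheet, _ = generate_counts(d, cat, truth=truth)
    table = run_contrasts(counts, sheet)
    labels = label_genes(table)
    conv_table, conv_summary = convergence_analysis(labels)
    return {"planted": planted, "identical": identical, "labels": labels,
            "table": conv_table, "summary": conv_summary}


@pytest.fixture(scope="session")
def runall_outputs(tmp_path_factory):
    """Full default-design pipeline run, once per session."""
    outdir = tmp_path_factory.mktemp("runall")
    report = run_all(SimDesign(seed=42), outdir)
    return {"outdir": outdir, "report": report}
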