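"""Shared fixtures: small synthetic cohorts generated once per session."""

from __future__ import annotations

import pathlib

import pandas as pd
import pytest

import clonotrack
from clonotrack import synthetic as syn


@pytest.fixture(scope="session")
def zero_noise_cohort(tmp_path_factory) -> dict:
    """A small zero-noise longitudinal cohort (3 participants, biopsy+urine)."""
    outdir = tmp_path_factory.mktemp("cohort_zero_noise")
    config = syn.example_cohort_config(
        seed=11, cells_per_sample=600, clones_per_participant=12, zero_noise=True
    )
    truth = syn.generate_cohort(config, outdir)
    return {"dir": pathlib.Path(outdir), "config": config, "truth": truth}


@pytest.fixture(scope="session")
def zero_noise_run(zero_noise_cohort, tmp_path_factory) -> dict:
    """Full pipeline output for the shared zero-noise cohort."""
    outdir = tmp_path_factory.mktemp("run_zero_noise")
    out = clonotrack.run(zero_noise_cohort["dir"] / "manifest.yaml", outdir=outdir / "out")
    tables = {
        p.stem: pd.read_csv(p, sep="\t") for p in out.glob("*.tsv")
    }
    return {**zero_noise_cohort, "out": out, "tables": tables}
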