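"""Shared fixtures: the default synthetic cohort and derived objects.

Heavy objects (cohort, normalized layers, CNV inference, the demo pipeline
runs) are session-scoped so the planted-recovery tests share one
computation.
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path

import numpy as np
import pytest

from clonetraj import (
    SimConfig,
    generate_cohort,
    infer_cnv,
    cnv_level,
    call_subclones,
    normalize_e,
    prepare_demo,
    run_pipeline,
)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(SimConfig(rng_seed=0))


@pytest.fixture(scope="session")
def e_default(default_cohort):
    return normalize_e(default_cohort.counts)


@pytest.fixture(scope="session")
def cnv_bundle(default_cohort, e_default):
    """CNV inference on the default cohort with a truth-based reference."""
    counts, genes, meta, truth = default_cohort
    ref = list(truth.loc[~truth["true_malignant"], "cell_id"][:300])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cnv = infer_cnv(e_default, genes, ref)
    levels = cnv_level(cnv, counts=counts)
    malignant_cells = list(truth.loc[truth["true_malignant"], "cell_id"])
    subclones = call_subclones(cnv, cells=malignant_cells)
    return {
        "cnv": cnv,
        "levels": levels,
        "subclones": subclones,
        "reference": ref,
        "malignant_cells": malignant_cells,
    }


def _tree_digest(directory: Path) -> str:
    h = hashlib.sha256()
    for f in sorted(Path(directory).glob("*.tsv")):
        h.update(f.name.encode())
        h.update(f.read_bytes())
    return h.hexdigest()


@pytest.fixture(scope="session")
def demo_runs(tmp_path_factory):
    """The full demo pipeline run twice with the same seed, plus digests."""
    import time

    results = []
    for tag in ("a", "b"):
        base = tmp_path_factory.mktemp(f"demo_{tag}")
        t0 = time.time()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            config, cohort = prepare_demo(base, seed=7)
            res = run_pipeline(config)
        results.append({
            "config": config,
            "cohort": cohort,
            "results": res,
            "digest": _tree_digest(config.output_dir),
            "elapsed": time.time() - t0,
        })
    return results
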