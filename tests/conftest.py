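"""Shared fixtures. The heavy gradient fits are session-scoped so the
module tests and the acceptance suite reuse a single fit each."""

import numpy as np
import pytest

from spotdecon import (
    FitConfig,
    NBGroundTruth,
    compute_proportions,
    fit_sc,
    fit_st,
    generate_nb_sc,
    generate_spots,
    split_generation_validation,
)

# fit sizes used throughout: epochs reduced from the 50k production default
# to the point where the moment-initialized optimizer has converged on
# problems of this size (see docs/methods.md)
SC_EPOCHS = 2000
ST_EPOCHS = 2000


@pytest.fixture(scope="session")
def sc_recovery():
    """NB single-cell data from known truth (3 types, 100 genes,
    200 cells/type) plus the maximum-likelihood fit."""
    truth = NBGroundTruth.random(100, 3, seed=42)
    sc, ann = generate_nb_sc(truth, 200, seed=43)
    params = fit_sc(sc, ann, FitConfig(epochs=SC_EPOCHS, seed=44))
    return {"truth": truth, "sc": sc, "ann": ann, "params": params}


@pytest.fixture(scope="session")
def pipeline():
    """Full two-step pipeline on semi-synthetic spots (5 types, 200 genes,
    200 spots, 10-30 cells per spot) with a generation/validation split."""
    truth = NBGroundTruth.random(200, 5, seed=11)
    sc, ann = generate_nb_sc(truth, 100, seed=12)
    (gen_sc, gen_ann), (val_sc, val_ann) = split_generation_validation(sc, ann, seed=13)
    ds = generate_spots(gen_sc, gen_ann, S=200, lb=10, ub=30, alpha=1.0, seed=14)
    params = fit_sc(val_sc, val_ann, FitConfig(epochs=SC_EPOCHS, seed=15))
    fit = fit_st(ds.spots, params, FitConfig(epochs=ST_EPOCHS, seed=16))
    pm = compute_proportions(fit)
    return {"dataset": ds, "params": params, "fit": fit, "proportions": pm}


@pytest.fixture(scope="session")
def withheld_type_fit():
    """Spots built from six types but deconvolved with a five-type
    reference: the sixth type is only visible to the dummy component."""
    truth = NBGroundTruth.random(150, 6, seed=21)
    sc, ann = generate_nb_sc(truth, 80, seed=22)
    (gen_sc, gen_ann), (val_sc, val_ann) = split_generation_validation(sc, ann, seed=23)
    ds = generate_spots(gen_sc, gen_ann, S=150, lb=10, ub=30, alpha=1.0, seed=24)
    withheld = "type5"
    keep = [c for c, l in zip(val_ann.cell_ids, val_ann.labels) if l != withheld]
    params = fit_sc(val_sc.subset_obs(keep), val_ann.subset(keep),
                    FitConfig(epochs=SC_EPOCHS, seed=25))
    fit = fit_st(ds.spots, params, FitConfig(epochs=ST_EPOCHS, seed=26))
    return {"dataset": ds, "withheld": withheld, "fit": fit, "params": params}
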