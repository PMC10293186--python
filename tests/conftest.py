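import numpy as np
import pytest

import paleoveg as pv


@pytest.fixture(scope="session")
def small_spec() -> pv.LandscapeSpec:
    """Desk-scale landscape preserving the default climatic span."""
    return pv.LandscapeSpec.for_grid(48, 48, seed=11)


@pytest.fixture(scope="session")
def small_stack(small_spec) -> pv.ClimateStack:
    return pv.generate_climate_stack(small_spec, age_ka=0.0)


@pytest.fixture(scope="session")
def small_truth(small_stack) -> pv.VegetationUnitMap:
    return pv.generate_true_vegetation(small_stack)


@pytest.fixture(scope="session")
def fitted_small_model(small_stack, small_truth):
    """One fitted model plus its background/test split, shared read-only."""
    occ = pv.sample_presences(small_truth, "DAF", 400, seed=7)
    train, test = pv.split_occurrences(occ, 0.25, seed=8)
    background = pv.sample_background(
        small_stack, 800, seed=9, variables=pv.NINE_PREDICTORS
    )
    model = pv.fit_maxent(
        train, background, small_stack, variables=pv.NINE_PREDICTORS
    )
    return {
        "model": model,
        "train": train,
        "test": test,
        "background": background,
        "stack": small_stack,
    }


def brute_force_auc(presence, background):
    """Exhaustive pair-counting oracle for the rank AUC."""
    wins = ties = 0
    for p in presence:
        for b in background:
            if p > b:
                wins += 1
            elif p == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(presence) * len(background))


def spearman_no_ties(x, y):
    """Textbook rank-difference formula, valid without ties."""
    x = np.asarray(x)
    y = np.asarray(y)
    rx = x.argsort().argsort().astype(float)
    ry = y.argsort().argsort().astype(float)
    d2 = ((rx - ry) ** 2).sum()
    n = len(x)
    return 1 - 6 * d2 / (n * (n**2 - 1))
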