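import numpy as np
import pandas as pd
import pytest

from genoscape import (
    CumulativeImportanceFunction,
    EnvStack,
    GradientForestModel,
    GradientForestParams,
    GridSpec,
    SyntheticConfig,
    filter_snps_by_maf,
    fit_gradient_forest,
    generate_bundle,
    select_significant_snps,
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Downscaled study conditions for fast unit tests."""
    return SyntheticConfig(grid_rows=30, grid_cols=30, n_snps=120, n_adaptive=20, seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_bundle(small_config)


@pytest.fixture(scope="session")
def small_model(small_bundle):
    filtered = filter_snps_by_maf(small_bundle.freqs, small_bundle.config.maf_threshold)
    model = fit_gradient_forest(
        filtered, small_bundle.env_at_sites(), GradientForestParams(), seed=small_bundle.config.seed
    )
    select_significant_snps(model, table=filtered)
    return model


def make_step_model(step_specs: dict[str, tuple[float, float, tuple[float, float]]]) -> GradientForestModel:
    """Hand-built model whose turnover functions are single steps.

    ``step_specs`` maps predictor -> (threshold, rise, (range_lo, range_hi)).
    A rise of 0 yields the all-zero function.
    """
    cif = {}
    for p, (thr, rise, (lo, hi)) in step_specs.items():
        if rise == 0:
            cif[p] = CumulativeImportanceFunction(p, np.array([lo]), np.array([0.0]))
        else:
            cif[p] = CumulativeImportanceFunction.from_splits(p, [(thr, rise)], start=lo)
    names = list(step_specs)
    return GradientForestModel(
        predictor_names=names,
        fits=[],
        cif=cif,
        overall={p: f.total_rise for p, f in cif.items()},
        params=GradientForestParams(),
        seed=0,
        env_at_sites=pd.DataFrame(columns=names),
    )


def make_stack(values_by_layer: dict[str, np.ndarray], cell_size: float = 1.0) -> EnvStack:
    """Single-purpose EnvStack builder for hand-computed examples."""
    names = list(values_by_layer)
    data = np.stack([np.asarray(values_by_layer[n], dtype=float) for n in names])
    rows, cols = data.shape[1:]
    grid = GridSpec(rows=rows, cols=cols, x_origin=0.0, y_origin=rows * cell_size, cell_size=cell_size)
    return EnvStack(grid, names, data)
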