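import numpy as np
import pytest

from aneumech import CoefficientSet, GeneratorConfig, Model, generate_curve, tables


@pytest.fixture(scope="session")
def aneurysm_ids():
    return tables.aneurysm_ids()


def reference_curve(specimen_id: str, model: Model, n_points: int = 200, **kwargs):
    """Noiseless curve generated from a published coefficient row over its
    published stretch window."""
    config = GeneratorConfig(
        coefficients=tables.reference_coefficients(specimen_id, model),
        lambda_max=tables.reference_window(specimen_id, model),
        n_points=n_points,
        **kwargs,
    )
    return generate_curve(config)


def neo_hookean_curve(c1: float = 0.1, lambda_max: float = 2.0, n_points: int = 50, **kw):
    config = GeneratorConfig(
        coefficients=CoefficientSet(Model.NEO_HOOKEAN, (c1,)),
        lambda_max=lambda_max,
        n_points=n_points,
        **kw,
    )
    return generate_curve(config)


def max_rel_err(recovered, truth) -> float:
    recovered = np.asarray(recovered, dtype=float)
    truth = np.asarray(truth, dtype=float)
    return float(np.max(np.abs(recovered - truth) / np.maximum(np.abs(truth), 1e-300)))
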