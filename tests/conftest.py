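import numpy as np
import pytest

from gwire import CorrelationCurve, OpticalContext, TwoModeParams, g2_model


@pytest.fixture(scope="session")
def context() -> OpticalContext:
    """He-Ne laser in aqueous KCl at 296 K (the package defaults)."""
    return OpticalContext()


def curve_from_params(
    params: TwoModeParams,
    angle_deg: float = 90.0,
    context: OpticalContext = OpticalContext(),
    n_points: int = 200,
) -> CorrelationCurve:
    """Noiseless forward-model curve on a log lag grid spanning the decay."""
    tau_max = params.tau_slow if np.isfinite(params.tau_slow) else params.tau_fast
    lag = np.geomspace(1e-3 * params.tau_fast, 1e3 * tau_max, n_points)
    return CorrelationCurve(
        lag_times=lag, g2=g2_model(lag, params), angle_deg=angle_deg, context=context
    )
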