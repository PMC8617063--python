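import numpy as np
import pytest

from thrombokit.kinetics import InhibitionSeries, morrison_velocity


@pytest.fixture
def tight_binding_series():
    """Noiseless Morrison inhibition series at the assay's enzyme level
    (Et = 0.8 nM, Ki' = 50 pM, inhibitor titrated through Et)."""
    it = np.array([0.0, 0.2, 0.4, 0.8, 1.2, 1.6, 2.4])
    fv = morrison_velocity(0.05, it, 0.8, 1.0)
    return InhibitionSeries(Et_nM=0.8, S_uM=100.0, It_nM=it,
                            fractional_velocity=fv), 50.0


@pytest.fixture
def triangular_thrombogram():
    """Piecewise-linear pulse: 0 until 2 min, to 300 nM at 5 min, back to
    0 at 20 min — every vertex on the sampling grid."""
    t = np.arange(0.0, 20.0 + 1e-9, 0.1)
    y = np.interp(t, [0.0, 2.0, 5.0, 20.0], [0.0, 0.0, 300.0, 0.0])
    return t, y
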