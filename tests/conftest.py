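"""Shared fixtures: reference AAR parameter sets used across the suite.

The thermodynamic values are the published AAR stability parameters
(urea two-state CD row, GdnHCl three-state CD and fluorescence rows, CD
melt); baseline coefficients are this package's synthetic-experiment
conventions, since instrument baselines are not part of the published
parameter tables.
"""

import pytest

from lemfold import Conditions, ThermalParams, ThreeStateParams, TwoStateParams


@pytest.fixture
def cond() -> Conditions:
    return Conditions()  # 298.15 K, R = 1.987e-3 kcal/(mol K)


@pytest.fixture
def urea_cd_truth() -> TwoStateParams:
    """AAR urea unfolding, CD probe: midpoint 4.3 M, m = 0.8 kcal/(mol M)."""
    return TwoStateParams(dG0=0.8 * 4.3, m=0.8, a1=1.0, b1=-0.005, c1=0.05, p1=0.005)


@pytest.fixture
def gdnhcl_cd_params() -> ThreeStateParams:
    """AAR GdnHCl three-state, CD probe row (dG_NI 1.5, dG_NU 4.3 kcal/mol)."""
    return ThreeStateParams(
        dG_NI0=1.5, m_NI=0.9, dG_NU0=4.3, m_NU=1.4,
        a1=1.0, b1=-0.01, c1=0.6, p1=0.01, e1=0.05, g1=0.005,
    )


@pytest.fixture
def gdnhcl_fluor_params() -> ThreeStateParams:
    """AAR GdnHCl three-state, fluorescence probe row (dG_NI 1.4, dG_NU 4.7)."""
    return ThreeStateParams(
        dG_NI0=1.4, m_NI=0.8, dG_NU0=4.7, m_NU=1.7,
        a1=1.0, b1=0.0, c1=0.6, p1=0.0, e1=0.0, g1=0.0,
    )


@pytest.fixture
def melt_cd_truth() -> ThermalParams:
    """AAR thermal melt, CD probe: Tm 43.3 degC (316.45 K), dH_vH 70 kcal/mol."""
    return ThermalParams(Tm=316.45, dH_vH=70.0, a1=1.0, b1=-0.001, c1=0.05, p1=0.0005)
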