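"""Published best-fit parameter sets for the two-step chronoamperometry runs.

Three poised-potential experiments on graphite-anode biofilms: wild type
stepped from −101 mV to 499 mV vs SHE (``WT_DE1``), wild type stepped from
−251 mV to 649 mV (``WT_DE2``), and the OmcS-deletion mutant stepped from
−251 mV to 649 mV (``DOMCS``).  Amounts are nmol, rates s⁻¹ (k_omc:
nmol⁻¹·s⁻¹), potentials V vs SHE.  All runs used the same electrode with
an exposed area of 3.3×10⁻³ m².
"""

from __future__ import annotations

from .model_core import ModelParameters, OmcSModelParameters

__all__ = [
    "ELECTRODE_AREA",
    "WT_DE1",
    "WT_DE2",
    "DOMCS",
    "DOMCS_VARIANT",
    "STEP_POTENTIALS",
    "KI_POINTS",
]

#: Exposed anode area, m².
ELECTRODE_AREA = 3.3e-3

WT_DE1 = ModelParameters(
    k_ac=1.33e-2,
    k_omc=4.99e-5,
    k_i_before=1.89e-2,
    k_i_after=2.06e-1,
    im_total=2555.0,
    omc_total=814.0,
    t_switch=60.0,
    electrode_area=ELECTRODE_AREA,
)

WT_DE2 = ModelParameters(
    k_ac=2.17e-2,
    k_omc=4.58e-5,
    k_i_before=2.26e-4,
    k_i_after=3.72e-1,
    im_total=2216.0,
    omc_total=723.0,
    t_switch=60.0,
    electrode_area=ELECTRODE_AREA,
)

#: ΔOmcS data fitted with the unmodified (wild-type-form) model.
DOMCS = ModelParameters(
    k_ac=2.11e-2,
    k_omc=5.01e-5,
    k_i_before=4.61e-3,
    k_i_after=3.16e-1,
    im_total=2908.0,
    omc_total=611.0,
    t_switch=60.0,
    electrode_area=ELECTRODE_AREA,
)

#: ΔOmcS saturating-flux variant.  The logistic transfer flux saturates at
#: 40 nmol·s⁻¹ — slightly above the acetate supply rate k_ac·(im_total−θ)
#: ≈ 29.7 nmol·s⁻¹, so the transfer step (not metabolism) pins IM_red near
#: θ and IM_red relaxes to it linearly after the potential step.
DOMCS_VARIANT = OmcSModelParameters(
    k_ac=2.11e-2,
    k_omc=40.0,
    k_i_before=4.61e-3,
    k_i_after=3.16e-1,
    im_total=2908.0,
    omc_total=611.0,
    t_switch=60.0,
    electrode_area=ELECTRODE_AREA,
    theta=1500.0,
    s=1.0,
)

#: Poised potentials (V vs SHE) of each run: (before, after).
STEP_POTENTIALS = {
    "wt_de1": (-0.101, 0.499),
    "wt_de2": (-0.251, 0.649),
    "domcs": (-0.251, 0.649),
}

#: The four wild-type (potential, interfacial rate) pairs used for the
#: Butler-Volmer analysis: before/after values of both step profiles.
KI_POINTS = [
    (-0.101, 1.89e-2),
    (0.499, 2.06e-1),
    (-0.251, 2.26e-4),
    (0.649, 3.72e-1),
]
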