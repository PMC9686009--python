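"""Physical constants and conventions shared across the toolkit.

All HU values follow the usual convention (air -1000, water 0).  Attenuation
coefficients are linear coefficients in 1/mm.  The kV spectrum is a small set
of discrete energy bins — enough to produce beam hardening without modelling
a full spectrum.
"""

from __future__ import annotations

import numpy as np

# Display/clamp ranges per modality.
HU_RANGES: dict[str, tuple[float, float]] = {
    "ct": (-1000.0, 3000.0),
    "mv": (-1000.0, 1400.0),
    "sct": (-1000.0, 3000.0),
}

MODALITIES = tuple(HU_RANGES)

# --- kV acquisition physics -------------------------------------------------
# Discrete spectrum bins (keV) with normalized weights, and the linear
# attenuation of water at each energy (1/mm, from standard mass-attenuation
# tables at unit density).
KV_ENERGIES_KEV = np.array([60.0, 70.0, 80.0, 90.0])
KV_WEIGHTS = np.array([0.20, 0.35, 0.30, 0.15])
MU_WATER_KV = np.array([0.0206, 0.0193, 0.0184, 0.0177])

#: Spectrum-weighted water attenuation used to convert reconstructed mu to HU.
MU_WATER_KV_EFF = float(np.sum(KV_WEIGHTS * MU_WATER_KV))

# High-Z materials (bone mineral, metal) attenuate disproportionately at low
# energies (photoelectric effect).  The excess attenuation above water-like
# scaling is boosted by (E_ref/E)**HARDENING_EXPONENT for HU above
# HARDENING_ONSET_HU, ramping in linearly until HARDENING_FULL_HU.
HARDENING_E_REF_KEV = 70.0
HARDENING_EXPONENT = 2.5
HARDENING_ONSET_HU = 150.0
HARDENING_FULL_HU = 500.0

# Metal is far denser than its HU (saturated at the scanner scale) implies:
# the water-like channel gains this excess density, ramped in between
# 2500 HU and 4000 HU.  This is what drives photon starvation behind metal.
METAL_DENSITY_EXCESS = 90.0

#: Water-equivalent length grid (mm) for the water-linearization correction.
WATER_LIN_LMAX_MM = 1500.0

# --- MV acquisition physics -------------------------------------------------
#: Linear attenuation of water at the effective MV energy (~2 MeV), 1/mm.
MU_WATER_MV = 0.005

# --- Default noise levels (photons per detector ray) ------------------------
KV_FLUENCE = 2.0e6
MV_FLUENCE = 3.5e5

# --- MV HU compression map --------------------------------------------------
# MV-CBCT HU as a piecewise-linear function of kV HU: soft-tissue contrast is
# compressed and the scale saturates toward 1400.  Strictly increasing so the
# map is invertible (the surrogate translator inverts it).
MV_COMPRESSION_KNOTS_CT = np.array([-1000.0, -100.0, 0.0, 100.0, 1500.0, 4000.0])
MV_COMPRESSION_KNOTS_MV = np.array([-1000.0, -60.0, 0.0, 60.0, 900.0, 1400.0])

# --- Phantom tissue HU assignments (kV ground truth) ------------------------
HU_AIR = -1000.0
HU_SOFT_TISSUE = 40.0
HU_BRAIN = 30.0
HU_ORAL_CAVITY = 20.0
HU_PAROTID = 10.0
HU_CORD = 35.0
HU_SKULL = 900.0
HU_MANDIBLE = 800.0
HU_TEETH = 1500.0

#: Ground-truth HU per metal insert material (pre-clamp; CT images saturate
#: at 3000 HU).
METAL_HU: dict[str, float] = {
    "aluminium_alloy": 3000.0,
    "titanium_alloy": 3500.0,
    "stainless_steel": 4000.0,
}

#: Relative electron density of the metal plug materials.
METAL_RED: dict[str, float] = {
    "aluminium_alloy": 2.43,
    "titanium_alloy": 3.73,
    "stainless_steel": 6.83,
}

# --- Metal segmentation thresholds (HU) -------------------------------------
CT_METAL_THRESHOLD = 2500.0
MV_METAL_THRESHOLD = 300.0

# --- P4 fusion band edges (HU), half-open [400, 800) ------------------------
FUSION_LOW_HU = 400.0
FUSION_HIGH_HU = 800.0

# --- Streak artifact index --------------------------------------------------
#: Soft-tissue pixels within this distance (mm) of metal enter the index.
ARTIFACT_RADIUS_MM = 30.0
#: Calibrated once against the no-metal kV simulation distribution (95th
#: percentile over seeds with margin); an index above this indicates streaks.
NO_METAL_ARTIFACT_THRESHOLD = 70.0
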