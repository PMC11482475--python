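"""Bundled reference dataset: a published ZnO nanoform cytotoxicity screen.

Eight zinc-based particles — six ZnO nanoforms (three uncoated, UC-1/2/3, and
three coated: AM = (3-aminopropyl)triethoxysilane, SA = stearic acid,
SO = silicone oil), micron-sized bulk ZnO and soluble ZnCl2 — screened in
human lung epithelial (A549) and mouse monocyte/macrophage (J774) cells with
three cytotoxicity endpoints (cellular ATP, %LDH released, CTB viability).

The tables here are the screen's printed summary numbers: per-endpoint
absolute potency exponents, physicochemical characterisation (TEM primary
size, BET surface area, DLS hydrodynamic size, polydispersity, zeta
potential) and ICP elemental contents in ppm. They serve as realistic inputs
for the consensus-ranking and descriptor-association stages and as regression
anchors for the test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PARTICLES = ["ZnO", "AM", "SA", "SO", "UC-1", "UC-2", "UC-3", "ZnCl2"]
NANOFORMS = ["AM", "SA", "SO", "UC-1", "UC-2", "UC-3"]
UNCOATED = ["UC-1", "UC-2", "UC-3"]
CELL_TYPES = ["A549", "J774"]
ENDPOINTS = ["ATP", "LDH", "CTB"]

# absolute potency exponents |beta| per particle x endpoint, as printed
_POTENCY_ABS = {
    # particle: (A549 ATP, A549 LDH, A549 CTB, J774 ATP, J774 LDH, J774 CTB)
    "ZnO": (0.120, 0.058, 0.089, 0.348, 0.189, 0.295),
    "AM": (0.173, 0.014, 0.093, 1.600, 0.170, 0.280),
    "SA": (0.177, 0.008, 0.106, 0.493, 0.174, 0.311),
    "SO": (0.140, 0.003, 0.146, 0.328, 0.172, 0.277),
    "UC-1": (0.160, 0.007, 0.121, 1.233, 0.170, 0.305),
    "UC-2": (0.213, 0.001, 0.173, 1.381, 0.170, 0.310),
    "UC-3": (0.152, 0.003, 0.176, 1.258, 0.172, 0.282),
    "ZnCl2": (0.265, 0.172, 0.220, 1.258, 0.145, 0.205),
}

# consensus average |beta| and rank as printed, for cross-checks
PUBLISHED_CONSENSUS = {
    "A549": {
        "ZnO": (0.089, 8), "AM": (0.093, 7), "SA": (0.097, 4), "SO": (0.096, 5),
        "UC-1": (0.096, 6), "UC-2": (0.129, 2), "UC-3": (0.110, 3), "ZnCl2": (0.219, 1),
    },
    "J774": {
        "ZnO": (0.277, 7), "AM": (0.683, 1), "SA": (0.326, 6), "SO": (0.259, 8),
        "UC-1": (0.569, 4), "UC-2": (0.620, 2), "UC-3": (0.571, 3), "ZnCl2": (0.536, 5),
    },
}

# physicochemical characterisation of the six nanoforms; NaN = not determined
_DESCRIPTORS = {
    # particle: (tem_size nm, betsa m2/g, dls_size nm, pdi, zeta mV)
    "AM": (30.0, 16.3, 212.0, 0.12, 19.3),
    "SA": (30.0, 29.0, 420.0, 0.13, np.nan),
    "SO": (30.0, 14.1, np.nan, np.nan, np.nan),
    "UC-1": (30.0, 21.6, 223.0, 0.19, 23.2),
    "UC-2": (40.0, 34.5, 278.0, 0.39, 23.0),
    "UC-3": (53.0, 11.9, 232.0, 0.14, 30.5),
}

# ICP-MS/ES elemental contents (ppm); "< detection" entries recorded as 0
_ELEMENTS_HEADER = PARTICLES
_ELEMENTS = {
    "As": (0.01, 0.04, 0.02, 0, 0.01, 0.09, 0.03, 0),
    "Al": (2.15, 75.47, 104.51, 41.28, 79.88, 50.67, 20.05, 1.20),
    "Ba": (0.27, 3.60, 1.95, 1.22, 2.28, 14.67, 0.29, 0.06),
    "Bi": (0.07, 0.02, 0.02, 0.01, 0, 0.03, 0.01, 0.23),
    "Ca": (17.92, 347.11, 876.69, 1067.04, 641.47, 1835.73, 20.43, 16.67),
    "Cd": (11.86, 0.42, 0.71, 0.12, 1.09, 0.62, 3.44, 2.22),
    "Ce": (0.02, 0.03, 0.02, 0.01, 0.01, 1.28, 1.11, 0.41),
    "Co": (0, 0.15, 0.09, 0.04, 0.11, 0.26, 0, 0),
    "Cr": (0.36, 0.46, 0.46, 0.23, 0.44, 4.21, 0.10, 0.33),
    "Cs": (0, 0, 0, 0.00, 0.00, 0, 0.02, 0.04),
    "Cu": (0.75, 3.24, 5.24, 2.50, 3.89, 1.63, 10.39, 0.38),
    "Dy": (0, 0, 0, 0, 0, 0.04, 0, 0),
    "Er": (0, 0, 0, 0, 0, 0.02, 0, 0),
    "Eu": (0, 0, 0, 0, 0, 0.01, 0, 0),
    "Fe": (3.35, 287.07, 19.36, 22.20, 18.24, 167.89, 10.18, 2.90),
    "Gd": (0, 0, 0, 0, 0, 0.12, 0.01, 0),
    "Hf": (0, 0.01, 0.02, 0, 0.01, 0, 0, 0),
    "Ho": (0, 0, 0, 0, 0, 0.01, 0, 0),
    "K": (8.19, 14.44, 13.80, 18.56, 11.25, 20.21, 10.59, 7.02),
    "La": (0, 0.01, 0.02, 0, 0.01, 10.67, 0.02, 0.02),
    "Lu": (0, 0, 0, 0, 0, 0, 0, 0),
    "Mg": (1.21, 112.06, 173.98, 220.07, 119.84, 538.70, 2.47, 1.01),
    "Mn": (0.17, 1.54, 4.40, 3.65, 1.01, 64.47, 0.13, 0.09),
    "Mo": (0.02, 0, 0, 0, 0.02, 0.07, 0.01, 0.02),
    "Na": (7.94, 780.06, 363.74, 1724.20, 949.48, 217.37, 11.68, 3.74),
    "Nb": (0, 0, 0.01, 0.01, 0.02, 0, 0, 0),
    "Nd": (0, 0.01, 0, 0, 0, 1.20, 0, 0.01),
    "Ni": (0.07, 0.63, 1.24, 0.59, 0.60, 21.68, 0.09, 0.19),
    "Pr": (0, 0, 0, 0, 0, 0.42, 0, 0),
    "Rb": (0.02, 0.02, 0.02, 0.02, 0.02, 0.04, 0.02, 0.02),
    "Sb": (0.01, 0.01, 0.08, 0.01, 0.03, 0.03, 0.01, 0.01),
    "Sc": (0, 0.03, 0, 0.06, 0.01, 0, 0, 0),
    "Si": (10.46, 1173.68, 46.21, 2718.81, 24.77, 36.37, 27.72, 9.04),
    "Sm": (0, 0, 0, 0, 0, 0.05, 0, 0),
    "Sr": (0.02, 1.80, 5.33, 4.32, 3.50, 13.56, 0.02, 0.06),
    "Ta": (0, 0, 0, 0, 0, 0, 0, 0),
    "Tb": (0, 0, 0, 0, 0, 0.01, 0, 0),
    "Th": (0, 0.02, 0.05, 0.01, 0.02, 0, 0.01, 0),
    "Ti": (0.97, 320.69, 382.85, 489.93, 228.36, 1.54, 1.32, 0.66),
    "Tm": (0, 0, 0, 0, 0, 0, 0, 0),
    "U": (0, 0, 0, 0, 0, 0.13, 0, 0),
    "V": (0.01, 0.05, 0.04, 0.02, 0.02, 0.07, 0.03, 0.02),
    "Yb": (0, 0, 0, 0, 0, 0.01, 0, 0),
    "Zn": (770268, 763278, 715683, 721911, 760799, 718568, 753952, 616834),
    "Zr": (0.05, 0.30, 0.91, 0.12, 0.47, 0.06, 0.02, 0.02),
}

#: transition-metal contaminants tallied for the derived descriptor (Zn, the
#: matrix element, is reported separately)
TRANSITION_METALS = [
    "Cd", "Co", "Cr", "Cu", "Fe", "Hf", "Mn", "Mo", "Nb", "Ni", "Sc", "Ta",
    "Ti", "V", "Zr",
]


def zno_potency(signed: bool = False) -> pd.DataFrame:
    """Tidy per-endpoint potency table: particle, cell_type, endpoint, beta_abs.

    With ``signed=True`` an extra ``beta_signed`` column restores the direction
    convention (ATP and CTB decline with dose, %LDH released rises).
    """
    from .association import signed_beta

    rows = []
    for particle, vals in _POTENCY_ABS.items():
        for i, (cell_type, endpoint) in enumerate(
            [(ct, ep) for ct in CELL_TYPES for ep in ENDPOINTS]
        ):
            rows.append(
                {
                    "particle": particle,
                    "cell_type": cell_type,
                    "endpoint": endpoint,
                    "beta_abs": vals[i],
                }
            )
    df = pd.DataFrame(rows)
    if signed:
        df["beta_signed"] = [
            signed_beta(b, ep) for b, ep in zip(df["beta_abs"], df["endpoint"])
        ]
    return df


def zno_elements() -> pd.DataFrame:
    """ICP elemental contents (ppm), particles as rows, elements as columns."""
    return pd.DataFrame(_ELEMENTS, index=_ELEMENTS_HEADER).astype(float)


def zno_descriptors() -> pd.DataFrame:
    """Physicochemical descriptor table for the six nanoforms, plus derived
    elemental descriptors (zn, transition_metals, total_metals, all ppm)."""
    df = pd.DataFrame(
        _DESCRIPTORS, index=["tem_size", "betsa", "dls_size", "pdi", "zeta"]
    ).T
    df.index.name = "particle"
    elements = zno_elements().loc[df.index]
    df["zn"] = elements["Zn"]
    df["transition_metals"] = elements[TRANSITION_METALS].sum(axis=1)
    df["total_metals"] = elements.sum(axis=1)
    return df
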