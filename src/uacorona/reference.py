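"""Bundled reference data for the six most abundant cow-milk proteins.

``MILK_PANEL`` carries the literature characterisation of the panel:
UniProt accession, molecular weight (Da), titration-derived net charge at pH 7,
residue count, and the molar concentration (mol/L) representing each
protein's share of total milk protein.

``IRON_EMIN`` carries published coarse-grained adsorption-energy minima
(kBT), preferred orientations (degrees) and closest-approach distances
(nm) for the panel on the three fcc facets of zero-valent iron, obtained
with the same united-atom model implemented in this package.  They are the
default energy inputs for the competitive-adsorption simulations.
"""

from __future__ import annotations

__all__ = ["MILK_PANEL", "IRON_EMIN", "IRON_FACETS"]

# abbreviation -> (uniprot, full name, MW Da, net charge e at pH 7,
#                  residue count, concentration mol/L)
MILK_PANEL: dict[str, tuple[str, str, float, float, int, float]] = {
    "AS1C": ("P02662", "alpha-s1-casein", 24528.00, -8.5, 214, 4e-4),
    "AS2C": ("P02663", "alpha-s2-casein", 26018.69, +4.5, 222, 1e-4),
    "BC":   ("P02666", "beta-casein", 25107.33, -4.5, 224, 4e-4),
    "ALAC": ("P00711", "alpha-lactalbumin", 16246.61, -5.0, 142, 0.9e-4),
    "BLAC": ("P02754", "beta-lactoglobulin", 19883.25, -6.0, 178, 2e-4),
    "BSA":  ("P02769", "bovine serum albumin", 69293.41, -4.5, 607, 0.1e-4),
}

IRON_FACETS = ("Fe-100", "Fe-110", "Fe-111")

# facet -> protein -> (E_min kBT, theta deg, phi deg, r_min nm)
IRON_EMIN: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "Fe-100": {
        "AS1C": (-343.07, 175, 100, 0.14),
        "AS2C": (-238.64, 335, 90, 0.08),
        "BC":   (-211.96, 315, 45, 0.04),
        "BSA":  (-202.99, 40, 60, 0.08),
        "ALAC": (-159.12, 80, 90, 0.18),
        "BLAC": (-142.98, 140, 110, 0.19),
    },
    "Fe-110": {
        "AS1C": (-325.92, 175, 100, 0.14),
        "AS2C": (-229.90, 335, 90, 0.07),
        "BSA":  (-189.87, 40, 60, 0.06),
        "BC":   (-162.43, 310, 45, 0.04),
        "BLAC": (-147.43, 140, 110, 0.18),
        "ALAC": (-144.41, 75, 90, 0.16),
    },
    "Fe-111": {
        "AS1C": (-330.36, 175, 100, 0.14),
        "AS2C": (-230.99, 330, 90, 0.10),
        "BC":   (-186.44, 310, 40, 0.02),
        "BSA":  (-178.25, 40, 60, 0.06),
        "ALAC": (-154.60, 75, 90, 0.15),
        "BLAC": (-151.56, 140, 110, 0.18),
    },
}
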