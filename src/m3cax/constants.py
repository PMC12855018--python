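"""Pinned numerical constants shared by code and test oracles.

Natural isotope abundances follow the standard terrestrial tables used by
low-resolution isotopologue-correction software.  Each entry maps an element
symbol to the fractional abundances of its isotopes ordered by mass shift
(+0, +1, +2, ... nominal mass units above the lightest isotope).  Every
vector sums to 1.
"""

from __future__ import annotations

#: Natural isotope abundance by element, indexed by nominal mass shift.
#: 13C abundance is 0.0107.
NATURAL_ABUNDANCE: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99632, 0.00368),
    "O": (0.99757, 0.00038, 0.00205),
    "S": (0.9493, 0.0076, 0.0429, 0.0, 0.0002),
    "P": (1.0,),
    "Si": (0.922297, 0.046832, 0.030871),
}

#: Percentile convention used by the RSD filter and its test oracle:
#: linear interpolation between order statistics (numpy's default).
PERCENTILE_METHOD = "linear"

#: Experimental groups in pseudo-time order.
GROUPS = ("Ctrl", "NonCax", "PreCax", "Cax")

#: Tissues profiled in the cohort design.  The tumour pool exists only in
#: tumour-bearing animals, so it never carries the Ctrl group.
TISSUES = (
    "plasma",
    "liver",
    "eWAT",
    "iWAT",
    "heart",
    "gastrocnemius",
    "soleus",
    "tumour",
)

#: Tissues eligible for the cross-tissue cachexia signature (tumour excluded).
CACHEXIA_TARGET_TISSUES = tuple(t for t in TISSUES if t != "tumour")

#: Metabolite classes used for annotation and contribution tables.
METABOLITE_CLASSES = (
    "amino acids",
    "carbohydrates",
    "energy",
    "lipids",
    "nucleosides",
    "organoheterocyclic",
    "other",
)
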