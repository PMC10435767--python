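"""IgG N-glycan peak nomenclature and derived glycosylation traits.

UHPLC chromatograms of 2-AB-labelled IgG N-glycans are integrated into 24
peaks (GP1-GP24), each expressed as a percentage of the total integrated
area. Six derived traits summarise structural features shared across peaks:
agalactosylated (G0), monogalactosylated (G1), digalactosylated (G2),
sialylated (S), core-fucosylated (F) and bisecting-GlcNAc (B) glycans.
"""

from __future__ import annotations

PEAKS: tuple[str, ...] = tuple(f"GP{i}" for i in range(1, 25))

#: Peaks poorly resolved on some plates; dropped from statistical analysis
#: and from derived-trait formulas.
DEFAULT_EXCLUDED: tuple[str, ...] = ("GP20", "GP21")

#: Derived glycosylation traits as sums of member peaks.
TRAIT_FORMULAS: dict[str, tuple[str, ...]] = {
    "G0": ("GP1", "GP2", "GP3", "GP4", "GP6"),
    "G1": ("GP7", "GP8", "GP9", "GP10", "GP11"),
    "G2": ("GP12", "GP13", "GP14", "GP15"),
    "S": ("GP16", "GP17", "GP18", "GP19", "GP22", "GP23", "GP24"),
    "F": (
        "GP1", "GP4", "GP6", "GP8", "GP9", "GP10", "GP11", "GP14",
        "GP15", "GP16", "GP18", "GP19", "GP23", "GP24",
    ),
    "B": ("GP3", "GP6", "GP10", "GP11", "GP13", "GP15", "GP19", "GP22", "GP24"),
}

TRAITS: tuple[str, ...] = tuple(TRAIT_FORMULAS)

#: The four trait groups whose member sets partition GP1-GP24 together with
#: the three structurally "orphan" peaks GP5, GP20 and GP21. G0/G1/G2/S are
#: mutually disjoint; F and B overlap them and are therefore emergent
#: properties of how trait totals are split over member peaks.
PARTITION_TRAITS: tuple[str, ...] = ("G0", "G1", "G2", "S")
ORPHAN_PEAKS: tuple[str, ...] = ("GP5", "GP20", "GP21")
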