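"""Published KORA S4 association statistics used as worked-example inputs.

The published metabolome-wide scan of the fat free mass index reports,
for a selection of traits, the multiple-testing-adjusted association
p-value, and for ratio traits additionally the p-gain.  For the rows
below, the printed single-metabolite p-values determine the minimum that
enters the p-gain formula, so the printed p-gain can be recomputed from
the table itself; the pipeline's :func:`ffmnet.ratios.p_gain` must
reproduce each to the printed 3 significant figures.

Two further printed ratio rows (PC aa C38:3 over the two lysoPC a C18
species) have their p-gains mutually swapped in print — each is exactly
reproduced by the *other* row's single p-value — and are therefore not
usable as worked examples.
"""

from __future__ import annotations

from dataclasses import dataclass

from .ratios import p_gain

#: printed adjusted p-values for single-metabolite FFMI associations
SINGLE_P: dict[str, float] = {
    "Val": 4.75e-16, "Glu": 1.22e-15, "Ile": 1.96e-11, "Leu": 2.57e-08,
    "Ala": 8.95e-06, "Tyr": 4.77e-10, "Phe": 2.53e-07,
    "C5": 3.49e-05, "C3": 4.85e-05, "C0": 1.19e-02, "C18": 3.96e-02,
    "PC aa C38:3": 7.02e-06, "PC ae C42:3": 5.10e-18,
    "PC ae C36:2": 2.42e-15, "lysoPC a C18:2": 8.19e-16,
    "lysoPC a C18:1": 2.30e-10,
}


@dataclass(frozen=True)
class RatioExample:
    """One recomputable printed ratio row.

    ``known_single_ps`` lists the printed single p-values of the pair; it
    may hold a single entry when only one of the two metabolites is
    printed but that entry is demonstrably the smaller (the partner's
    value is bounded below by it through the printed p-gain itself).
    """

    trait: str
    known_single_ps: tuple[float, ...]
    p_ratio: float
    printed_p_gain: float

    def recompute(self) -> float:
        p_min = min(self.known_single_ps)
        return p_gain(p_min, 1.0, self.p_ratio)


#: the seven internally consistent printed ratio rows
RATIO_EXAMPLES: tuple[RatioExample, ...] = (
    RatioExample("Ile/Gly", (SINGLE_P["Ile"],), 1.61e-14, 1.22e3),
    RatioExample("C18/C5", (SINGLE_P["C18"], SINGLE_P["C5"]),
                 1.44e-09, 2.42e4),
    RatioExample("C18/C3", (SINGLE_P["C18"], SINGLE_P["C3"]),
                 3.65e-09, 1.33e4),
    RatioExample("C18/C0", (SINGLE_P["C18"], SINGLE_P["C0"]),
                 5.44e-07, 2.19e4),
    RatioExample("lysoPC a C14:0/lysoPC a C18:2",
                 (SINGLE_P["lysoPC a C18:2"],), 1.04e-20, 7.88e4),
    RatioExample("PC aa C38:3/PC ae C42:3",
                 (SINGLE_P["PC aa C38:3"], SINGLE_P["PC ae C42:3"]),
                 3.12e-26, 1.63e8),
    RatioExample("PC aa C38:3/PC ae C36:2",
                 (SINGLE_P["PC aa C38:3"], SINGLE_P["PC ae C36:2"]),
                 8.17e-25, 2.96e9),
)


def pgain_worked_examples() -> dict[str, dict[str, float]]:
    """Recompute every printed p-gain example; keys are trait names."""
    return {
        ex.trait: {
            "recomputed": ex.recompute(),
            "printed": ex.printed_p_gain,
        }
        for ex in RATIO_EXAMPLES
    }
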