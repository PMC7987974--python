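"""Per-drug generative presets.

A preset pins the two drug-specific quantities of the elongation model: the
per-translocation retention probability ``q`` (how long the drug stays on a
translating ribosome) and the observable conditional next-error frequency
``E_f^next`` at an anchor distance d. The microscopic bound-state misreading
probability is back-solved from the observable,

    m * w = E_f^next(d) / q**(d + 1),

because d + 1 translocation events separate the two decoding steps of a
cluster with d correct residues in between.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources


@dataclass(frozen=True)
class AGAPreset:
    name: str
    q: float
    efnext: dict[int, float] = field(default_factory=dict)  # anchor d -> value
    group: str | None = None
    max_misreading_conc_um: float | None = None
    q_source: str = "assumed"

    def __post_init__(self) -> None:
        if not (0.0 <= self.q <= 1.0):
            raise ValueError(f"{self.name}: q must be in [0, 1]")
        for d, v in self.efnext.items():
            if d < 0 or not (0.0 <= v <= 1.0):
                raise ValueError(f"{self.name}: bad efnext anchor ({d}, {v})")

    def bound_misreading(self, d: int | None = None) -> float:
        """Bound-state per-codon misreading probability m*w.

        Back-solved from the E_f^next anchor at distance ``d`` (or at the
        preset's only/smallest anchor when ``d`` is not an anchor).
        """
        if not self.efnext:
            raise ValueError(f"{self.name}: preset has no efnext anchor")
        if d is not None and d in self.efnext:
            anchor = d
        else:
            anchor = min(self.efnext)
        mw = self.efnext[anchor] / self.q ** (anchor + 1)
        if mw > 1.0 + 1e-12:
            raise ValueError(
                f"{self.name}: back-solved misreading probability {mw:.3g} > 1"
            )
        return min(mw, 1.0)

    def expected_efnext(self, d: int) -> float:
        """Model-implied observable E_f^next at distance d."""
        return self.bound_misreading(d) * self.q ** (d + 1)


@lru_cache(maxsize=1)
def load_presets() -> dict[str, AGAPreset]:
    text = resources.files("agaclust.data").joinpath("aga_presets.json").read_text()
    raw = json.loads(text)
    presets = {}
    for name, entry in raw["presets"].items():
        presets[name] = AGAPreset(
            name=name,
            q=entry["q"],
            efnext={int(k): float(v) for k, v in entry.get("efnext", {}).items()},
            group=entry.get("group"),
            max_misreading_conc_um=entry.get("max_misreading_conc_um"),
            q_source=entry.get("q_source", "assumed"),
        )
    return presets


def get_preset(name: str) -> AGAPreset:
    presets = load_presets()
    for key in (name, name.capitalize()):
        if key in presets:
            return presets[key]
    raise KeyError(f"no preset named {name!r}; available: {sorted(presets)}")
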