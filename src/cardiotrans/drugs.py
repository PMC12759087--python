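"""Hill-equation pharmacology.

A drug is described by its blocking potency pIC50 per target protein
(pIC50 = 6 - log10(IC50 in uM); larger means more potent) together with a
Hill coefficient per target (1 = non-cooperative binding, the default used
throughout the translation pipeline).  At a concentration ``C`` a potency
renders to a pharmacological scaling factor

    s = 1 / (1 + (C / IC50)**h),   0 < s <= 1,

which multiplies the target's maximal conductance or pump rate.  Only
inhibition is modelled: s = 1 means no block, s -> 0 complete block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SHARED_TARGETS",
    "RAT_TARGETS",
    "HUMAN_TARGETS",
    "IDENTIFIABLE_TARGETS",
    "DrugSpec",
    "scaling_factor",
    "pic50_to_ic50",
    "ic50_to_pic50",
    "scaling_factors",
    "sample_virtual_drugs",
]

#: Proteins represented in the rat model (all are shared with human).
RAT_TARGETS = (
    "Nav1.5-late",
    "Cav1.2",
    "Kv4.3",
    "Kir2.1",
    "RyR2",
    "SERCA2",
    "NCX1",
    "NKA",
)

#: Proteins present only in the human model.
HUMAN_ONLY_TARGETS = ("Nav1.5-peak", "hERG", "KvLQT1/minK")

HUMAN_TARGETS = RAT_TARGETS + HUMAN_ONLY_TARGETS

#: The 8-protein roster shared by both species (candidates for inference).
SHARED_TARGETS = RAT_TARGETS

#: Targets whose potencies are identifiable from SL/Ca biomarkers.
IDENTIFIABLE_TARGETS = ("RyR2", "SERCA2", "NCX1")

_ALL_KNOWN = frozenset(HUMAN_TARGETS)


def pic50_to_ic50(pic50: float | np.ndarray) -> float | np.ndarray:
    """IC50 in uM from pIC50 (pIC50 = 6 - log10(IC50/uM))."""
    return 10.0 ** (6.0 - np.asarray(pic50, dtype=float))


def ic50_to_pic50(ic50_um: float | np.ndarray) -> float | np.ndarray:
    """pIC50 from IC50 in uM; raises for non-positive IC50."""
    ic50 = np.asarray(ic50_um, dtype=float)
    if np.any(ic50 <= 0.0):
        raise ValueError("IC50 must be strictly positive (uM)")
    return 6.0 - np.log10(ic50)


def scaling_factor(
    pic50: float | np.ndarray,
    conc_um: float | np.ndarray,
    hill: float = 1.0,
) -> float | np.ndarray:
    """Pharmacological scaling factor s = 1/(1 + (C/10^(6-pIC50))^h).

    ``s`` is in (0, 1]; s = 1 at zero concentration and s = 0.5 at
    C = IC50 for any Hill coefficient.
    """
    if hill <= 0.0:
        raise ValueError("Hill coefficient must be > 0")
    conc = np.asarray(conc_um, dtype=float)
    if np.any(conc < 0.0):
        raise ValueError("drug concentration must be >= 0 uM")
    ic50 = pic50_to_ic50(pic50)
    s = 1.0 / (1.0 + (conc / ic50) ** hill)
    if np.isscalar(conc_um) and np.isscalar(pic50):
        return float(s)
    return s


@dataclass(frozen=True)
class DrugSpec:
    """Per-target blocking potencies of one (possibly virtual) drug.

    ``potencies`` maps protein name -> pIC50; ``hill`` maps protein name ->
    Hill coefficient (defaults to 1 for targets not listed).
    """

    name: str
    potencies: Mapping[str, float]
    hill: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for target in self.potencies:
            if target not in _ALL_KNOWN:
                raise ValueError(f"unknown drug target {target!r}")
        for target, h in self.hill.items():
            if target not in _ALL_KNOWN:
                raise ValueError(f"unknown drug target {target!r}")
            if h <= 0.0:
                raise ValueError(f"Hill coefficient for {target} must be > 0")

    def hill_for(self, target: str) -> float:
        return float(self.hill.get(target, 1.0))

    def scaling_at(self, conc_um: float) -> dict[str, float]:
        """Render the drug to per-target scaling factors at one concentration."""
        return {
            t: scaling_factor(p, conc_um, self.hill_for(t))
            for t, p in self.potencies.items()
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "potencies": dict(self.potencies),
                "hill": dict(self.hill),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DrugSpec":
        obj = json.loads(text)
        return cls(
            name=obj["name"],
            potencies={k: float(v) for k, v in obj["potencies"].items()},
            hill={k: float(v) for k, v in obj.get("hill", {}).items()},
        )


def scaling_factors(
    drug: DrugSpec, concentrations_um: Sequence[float]
) -> dict[float, dict[str, float]]:
    """Scaling-factor maps for each concentration of a series."""
    concs = [float(c) for c in concentrations_um]
    if any(c <= 0 for c in concs):
        raise ValueError("concentrations must be > 0 uM")
    return {c: drug.scaling_at(c) for c in concs}


def sample_virtual_drugs(
    targets: Iterable[str],
    pic50_range: tuple[float, float] = (5.0, 6.0),
    n: int = 1,
    seed: int | np.random.Generator | None = None,
    name_prefix: str = "virtual",
) -> list[DrugSpec]:
    """Draw ``n`` virtual drugs, each target's pIC50 uniform in ``pic50_range``.

    Sampling is uniform on the pIC50 scale (not the IC50 scale).  A fixed
    ``seed`` makes the batch reproducible.
    """
    targets = tuple(targets)
    if not targets:
        raise ValueError("target list must be non-empty")
    for t in targets:
        if t not in _ALL_KNOWN:
            raise ValueError(f"unknown drug target {t!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = map(float, pic50_range)
    if hi < lo:
        raise ValueError("pic50_range must satisfy lo <= hi")
    rng = np.random.default_rng(seed)
    draws = rng.uniform(lo, hi, size=(n, len(targets)))
    return [
        DrugSpec(
            name=f"{name_prefix}-{i:03d}",
            potencies={t: float(draws[i, j]) for j, t in enumerate(targets)},
        )
        for i in range(n)
    ]
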