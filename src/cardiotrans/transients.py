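"""Transient biomarkers, abnormality detection and drug effects.

Seven biomarkers characterise each transient (sarcomere length or
intracellular [Ca2+]): the resting value, the amplitude measure
(percentage shortening ``Short`` for SL, ``CaAmp`` for Ca), time from
stimulus to peak, times from peak to 50 % and 90 % return, and the extreme
rates of the rising and falling phases.  Simulated biomarkers are taken
from the last beat of a paced run; abnormality screening (alternans,
fluctuations) inspects the last two beats.

Conventions (deterministic by construction):
  * the resting value is the sample at the stimulus instant of the beat;
  * the peak is the first sample attaining the within-beat extremum
    (minimum for SL, maximum for Ca);
  * return times are located by linear interpolation between samples;
  * rates are central differences on the output grid (one-sided at the
    window edges).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SL_BIOMARKERS",
    "CA_BIOMARKERS",
    "ALL_BIOMARKERS",
    "Transient",
    "BiomarkerSet",
    "AbnormalityFlags",
    "DrugEffectTable",
    "extract_biomarkers",
    "detect_abnormalities",
    "drug_effect",
    "classify_effect",
]

SL_BIOMARKERS = ("SLRes", "Short", "SLTP", "SLTR50", "SLTR90", "dSLMaxC", "dSLMaxR")
CA_BIOMARKERS = ("CaRes", "CaAmp", "CaTP", "CaTR50", "CaTR90", "dCaMax", "dCaMin")
#: The 14 characteristic biomarkers, SL first.
ALL_BIOMARKERS = SL_BIOMARKERS + CA_BIOMARKERS

#: Beat-to-beat amplitude ratio above which alternans is flagged (strict >).
ALTERNANS_RATIO = 1.1
#: Fluctuation rate threshold, in signal units per ms (um/ms or uM/ms).
FLUCTUATION_RATE = 1.0e-3


@dataclass(frozen=True)
class Transient:
    """Uniformly sampled SL (um) or Ca (uM) time series with stimulus marks."""

    time: np.ndarray  # ms, uniform, strictly increasing
    value: np.ndarray
    kind: Literal["SL", "Ca"]
    stimulus_times: np.ndarray  # ms
    pacing_frequency: float  # Hz

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        value = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "value", value)
        object.__setattr__(
            self, "stimulus_times", np.asarray(self.stimulus_times, dtype=float)
        )
        if self.kind not in ("SL", "Ca"):
            raise ValueError(f"kind must be 'SL' or 'Ca', got {self.kind!r}")
        if time.ndim != 1 or time.size < 2 or time.size != value.size:
            raise ValueError("time and value must be 1-D arrays of equal length >= 2")
        dt = np.diff(time)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time grid must be uniform and strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def shifted(self, offset_ms: float) -> "Transient":
        """Same waveform on a shifted clock (stimuli shifted alike)."""
        return Transient(
            self.time + offset_ms,
            self.value,
            self.kind,
            self.stimulus_times + offset_ms,
            self.pacing_frequency,
        )


@dataclass(frozen=True)
class BiomarkerSet:
    """The 7 characteristic biomarkers of one transient.

    Undefined biomarkers (e.g. no recovery crossing before the beat ends)
    are NaN and propagate as missing values downstream.
    """

    kind: Literal["SL", "Ca"]
    values: Mapping[str, float]

    def __getitem__(self, name: str) -> float:
        return float(self.values[name])

    def get(self, name: str, default: float = math.nan) -> float:
        return float(self.values.get(name, default))

    @property
    def names(self) -> tuple[str, ...]:
        return SL_BIOMARKERS if self.kind == "SL" else CA_BIOMARKERS

    def as_series(self) -> pd.Series:
        return pd.Series({k: self.values.get(k, math.nan) for k in self.names})


@dataclass(frozen=True)
class AbnormalityFlags:
    alternans: bool
    fluctuation_pre_peak: bool
    fluctuation_post_peak: bool

    @property
    def any(self) -> bool:
        return self.alternans or self.fluctuation_pre_peak or self.fluctuation_post_peak


def _beat_slice(tr: Transient, stim_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Samples of the beat starting at stimulus ``stim_index`` ([stim, next stim))."""
    stims = tr.stimulus_times
    t0 = stims[stim_index]
    t1 = stims[stim_index + 1] if stim_index + 1 < len(stims) else tr.time[-1] + tr.dt
    sel = (tr.time >= t0 - 1e-9) & (tr.time < t1 - 1e-9)
    return tr.time[sel], tr.value[sel]


def _rates(t: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Central-difference rates, one-sided at the ends (units per ms)."""
    return np.gradient(v, t)


def _return_time(
    t: np.ndarray, v: np.ndarray, i_peak: int, level: float, upward: bool
) -> float:
    """Time from the peak to the first crossing of ``level``, interpolated.

    ``upward`` selects crossings where the signal rises through the level
    (SL recovery); otherwise falls through it (Ca decay).  NaN if the beat
    ends before the crossing.
    """
    seg = v[i_peak:]
    ts = t[i_peak:]
    if upward:
        hit = np.nonzero(seg >= level)[0]
    else:
        hit = np.nonzero(seg <= level)[0]
    hit = hit[hit > 0]
    if hit.size == 0:
        return math.nan
    j = int(hit[0])
    v0, v1 = seg[j - 1], seg[j]
    if v1 == v0:
        tc = ts[j]
    else:
        tc = ts[j - 1] + (level - v0) / (v1 - v0) * (ts[j] - ts[j - 1])
    return float(tc - t[i_peak])


def extract_biomarkers(tr: Transient, beat: Literal["last"] = "last") -> BiomarkerSet:
    """Extract the 7 characteristic biomarkers from the last beat.

    The resting value is the sample at the beat's stimulus instant; the peak
    is the first within-beat extremum; return times run from the peak to
    50 %/90 % recovery of the beat amplitude with linear interpolation.
    """
    if beat != "last":
        raise ValueError("only the last beat is analysed")
    if len(tr.stimulus_times) < 1:
        raise ValueError("transient carries no stimulus annotation")
    t, v = _beat_slice(tr, len(tr.stimulus_times) - 1)
    if t.size < 3:
        raise ValueError("last beat covers fewer than 3 samples")

    rest = float(v[0])
    t_stim = float(t[0])
    is_sl = tr.kind == "SL"
    i_peak = int(np.argmin(v) if is_sl else np.argmax(v))
    peak = float(v[i_peak])
    amp = (rest - peak) if is_sl else (peak - rest)
    tp = float(t[i_peak] - t_stim)

    rates = _rates(t, v)
    vals: dict[str, float] = {}

    if amp <= 0 or i_peak == 0:
        # flat or non-contracting beat: amplitude 0, rates 0, times undefined
        if is_sl:
            vals = {
                "SLRes": rest,
                "Short": 0.0,
                "SLTP": math.nan,
                "SLTR50": math.nan,
                "SLTR90": math.nan,
                "dSLMaxC": 0.0,
                "dSLMaxR": 0.0,
            }
        else:
            vals = {
                "CaRes": rest,
                "CaAmp": 0.0,
                "CaTP": math.nan,
                "CaTR50": math.nan,
                "CaTR90": math.nan,
                "dCaMax": 0.0,
                "dCaMin": 0.0,
            }
        return BiomarkerSet(tr.kind, vals)

    if is_sl:
        tr50 = _return_time(t, v, i_peak, peak + 0.5 * amp, upward=True)
        tr70 = _return_time(t, v, i_peak, peak + 0.7 * amp, upward=True)
        tr90 = _return_time(t, v, i_peak, peak + 0.9 * amp, upward=True)
        vals = {
            "SLRes": rest,
            "Short": 100.0 * amp / rest,
            "SLTP": tp,
            "SLTR50": tr50,
            "SLTR90": tr90,
            "dSLMaxC": float(np.min(rates[: i_peak + 1])),
            "dSLMaxR": float(np.max(rates[i_peak:])),
            # Table-2b style stimulus-referenced return times (derived)
            "SLTD70": tp + tr70 if not math.isnan(tr70) else math.nan,
            "SLTD90": tp + tr90 if not math.isnan(tr90) else math.nan,
        }
    else:
        tr50 = _return_time(t, v, i_peak, peak - 0.5 * amp, upward=False)
        tr90 = _return_time(t, v, i_peak, peak - 0.9 * amp, upward=False)
        vals = {
            "CaRes": rest,
            "CaAmp": amp,
            "CaPeak": peak,
            "CaTP": tp,
            "CaTR50": tr50,
            "CaTR90": tr90,
            "dCaMax": float(np.max(rates[: i_peak + 1])),
            "dCaMin": float(np.min(rates[i_peak:])),
        }
    return BiomarkerSet(tr.kind, vals)


def _beat_amp_and_windows(
    tr: Transient, stim_index: int
) -> tuple[float, np.ndarray, np.ndarray]:
    """Beat amplitude plus pre-peak and post-peak rate windows.

    The stimulus sample itself is excluded from the pre-peak window and the
    peak sample from both windows (stimulus-artefact / turning-point guard).
    """
    t, v = _beat_slice(tr, stim_index)
    is_sl = tr.kind == "SL"
    i_peak = int(np.argmin(v) if is_sl else np.argmax(v))
    amp = abs(float(v[0]) - float(v[i_peak]))
    rates = _rates(t, v)
    pre = rates[1:i_peak]
    post = rates[i_peak + 1 :]
    return amp, pre, post


def detect_abnormalities(tr: Transient) -> AbnormalityFlags:
    """Screen the last two beats for alternans and fluctuations.

    Alternans: larger/smaller beat amplitude ratio strictly above 1.1.
    Fluctuations: rates of the wrong sign beyond 0.001 units/ms in the
    pre-peak or post-peak window of either beat (for SL, positive before the
    peak or negative after it; mirrored signs for Ca).
    """
    if len(tr.stimulus_times) < 2:
        raise ValueError("abnormality screening requires at least 2 beats")
    i_last = len(tr.stimulus_times) - 1
    a2, pre2, post2 = _beat_amp_and_windows(tr, i_last)
    a1, pre1, post1 = _beat_amp_and_windows(tr, i_last - 1)

    lo, hi = sorted((a1, a2))
    alternans = bool(lo > 0 and hi / lo > ALTERNANS_RATIO) or (lo == 0 and hi > 0)

    thr = FLUCTUATION_RATE
    if tr.kind == "SL":
        pre_bad = any(w.size and np.max(w) > thr for w in (pre1, pre2))
        post_bad = any(w.size and np.min(w) < -thr for w in (post1, post2))
    else:
        pre_bad = any(w.size and np.min(w) < -thr for w in (pre1, pre2))
        post_bad = any(w.size and np.max(w) > thr for w in (post1, post2))
    return AbnormalityFlags(alternans, bool(pre_bad), bool(post_bad))


def drug_effect(baseline: BiomarkerSet, drugged: BiomarkerSet) -> dict[str, float]:
    """Percentage change of each biomarker, 100*(drug - base)/base.

    Zero or missing baseline entries yield NaN (undefined effect), never an
    exception.
    """
    if baseline.kind != drugged.kind:
        raise ValueError("biomarker sets must share the same kind")
    out: dict[str, float] = {}
    for name in baseline.names:
        b = baseline.get(name)
        d = drugged.get(name)
        if math.isnan(b) or math.isnan(d) or b == 0.0:
            out[name] = math.nan
        else:
            out[name] = 100.0 * (d - b) / b
    return out


#: Classification thresholds per scheme: (positive >=, negative <=), in %.
CLASSIFICATION_SCHEMES = {
    "rat_sim": (5.0, -5.0),
    "human": (10.0, -25.0),
}


def classify_effect(
    effect_pct: float, scheme: Literal["rat_sim", "human"]
) -> Literal["positive", "negative", "absent"]:
    """Classify a % drug effect as positive / negative / absent."""
    try:
        pos, neg = CLASSIFICATION_SCHEMES[scheme]
    except KeyError:
        raise ValueError(f"unknown classification scheme {scheme!r}") from None
    if not math.isfinite(effect_pct):
        raise ValueError("effect must be finite")
    if effect_pct >= pos:
        return "positive"
    if effect_pct <= neg:
        return "negative"
    return "absent"


#: Plausibility range for included drug effects, in %.
INCLUSION_RANGE = (-100.0, 500.0)


@dataclass
class DrugEffectTable:
    """Per-concentration, per-biomarker % drug effects.

    The tidy table has columns ``concentration_uM, biomarker, effect_pct,
    included``; the inclusion mask applies the plausibility range (default
    [-100, 500] %) and excludes NaN effects.
    """

    table: pd.DataFrame
    species: str = ""
    inclusion_range: tuple[float, float] = INCLUSION_RANGE

    @classmethod
    def from_effects(
        cls,
        effects: Mapping[float, Mapping[str, float]],
        species: str = "",
        inclusion_range: tuple[float, float] = INCLUSION_RANGE,
    ) -> "DrugEffectTable":
        lo, hi = inclusion_range
        rows = []
        for conc in sorted(effects):
            for biomarker, eff in effects[conc].items():
                ok = bool(np.isfinite(eff) and lo <= eff <= hi)
                rows.append(
                    {
                        "concentration_uM": float(conc),
                        "biomarker": biomarker,
                        "effect_pct": float(eff),
                        "included": ok,
                    }
                )
        return cls(pd.DataFrame(rows), species=species, inclusion_range=inclusion_range)

    @property
    def concentrations(self) -> np.ndarray:
        return np.sort(self.table["concentration_uM"].unique())

    def effect(self, conc_um: float, biomarker: str) -> float:
        sel = self.table[
            (self.table["concentration_uM"] == conc_um)
            & (self.table["biomarker"] == biomarker)
        ]
        if sel.empty:
            return math.nan
        return float(sel["effect_pct"].iloc[0])

    def matrix(self, biomarkers: Iterable[str] = ALL_BIOMARKERS) -> pd.DataFrame:
        """Wide (biomarker x concentration) view; excluded entries are NaN."""
        tab = self.table.copy()
        tab.loc[~tab["included"], "effect_pct"] = np.nan
        wide = tab.pivot_table(
            index="biomarker",
            columns="concentration_uM",
            values="effect_pct",
            dropna=False,
        )
        return wide.reindex(list(biomarkers))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, species: str = "") -> "DrugEffectTable":
        tab = pd.read_csv(path)
        required = {"concentration_uM", "biomarker", "effect_pct", "included"}
        if not required.issubset(tab.columns):
            raise ValueError(f"drug-effect CSV must have columns {sorted(required)}")
        return cls(tab, species=species)
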