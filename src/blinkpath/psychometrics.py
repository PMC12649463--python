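"""Likert-scale scoring, reliability, descriptives and correlations.

Scores the BFI-2 (60 items, five domains of 12 items each on a 1-5
response scale, domain score = item mean after reversing reverse-keyed
items) and the PSS-14 (14 items on a 0-4 scale, total = item sum after
reversing the positively worded items; range 0-56).  The shipped keying
maps are the published instrument defaults and can be overridden from a
JSON config.  Descriptive statistics use the adjusted Fisher-Pearson
skewness (G1) and small-sample-corrected excess kurtosis (G2), the
estimators printed by mainstream statistics packages.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Dict, Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScaleDefinition",
    "DescriptiveStats",
    "BFI2_DOMAINS",
    "BFI2_ITEM_MAP",
    "PSS14",
    "reverse_item",
    "score_scale",
    "cronbach_alpha",
    "descriptives",
    "pearson_matrix",
    "PearsonResult",
    "score_participants",
    "load_scale_definitions",
]


@dataclass(frozen=True)
class ScaleDefinition:
    """Scoring rule for one scale: response range, keying, aggregation."""

    name: str
    item_count: int
    response_min: float
    response_max: float
    reverse_keyed_items: frozenset  # 1-based indices within the scale's item vector
    aggregation: str  # "mean" | "sum"

    def __post_init__(self) -> None:
        if self.response_min >= self.response_max:
            raise ValueError("response_min must be < response_max")
        bad = [i for i in self.reverse_keyed_items if not 1 <= i <= self.item_count]
        if bad:
            raise ValueError(f"reverse-keyed indices out of range: {bad}")
        if self.aggregation not in ("mean", "sum"):
            raise ValueError("aggregation must be 'mean' or 'sum'")


# --- instrument defaults (published scoring keys, not study data) -----------

#: BFI-2 questionnaire item numbers per domain; negative = reverse-keyed.
BFI2_ITEM_MAP: Dict[str, tuple] = {
    "extraversion": (1, 6, -11, -16, 21, -26, -31, -36, 41, 46, -51, 56),
    "agreeableness": (2, 7, -12, -17, -22, 27, 32, -37, -42, -47, 52, 57),
    "conscientiousness": (-3, -8, 13, 18, -23, -28, 33, 38, 43, -48, 53, -58),
    "negative_emotionality": (-4, -9, 14, 19, -24, -29, 34, 39, -44, -49, 54, 59),
    "open_mindedness": (-5, 10, 15, 20, -25, -30, 35, 40, -45, -50, -55, 60),
}

BFI2_DOMAINS: Dict[str, ScaleDefinition] = {
    domain: ScaleDefinition(
        name=f"bfi2_{domain}",
        item_count=12,
        response_min=1,
        response_max=5,
        reverse_keyed_items=frozenset(
            pos + 1 for pos, item in enumerate(items) if item < 0
        ),
        aggregation="mean",
    )
    for domain, items in BFI2_ITEM_MAP.items()
}

#: PSS-14 with its positively worded items reverse-keyed; total is a sum.
PSS14 = ScaleDefinition(
    name="pss14",
    item_count=14,
    response_min=0,
    response_max=4,
    reverse_keyed_items=frozenset({4, 5, 6, 7, 9, 10, 13}),
    aggregation="sum",
)


def load_scale_definitions(path) -> Dict[str, ScaleDefinition]:
    """Load keying config JSON: per scale `reverse_items`, `aggregation`, range."""
    with open(path) as fh:
        cfg = json.load(fh)
    out = {}
    for name, c in cfg.items():
        out[name] = ScaleDefinition(
            name=name,
            item_count=c["item_count"],
            response_min=c["response_min"],
            response_max=c["response_max"],
            reverse_keyed_items=frozenset(c.get("reverse_items", ())),
            aggregation=c.get("aggregation", "mean"),
        )
    return out


# --- scoring ----------------------------------------------------------------


def reverse_item(x: float, response_min: float, response_max: float) -> float:
    """Reverse-score a Likert response: min + max − x (an involution)."""
    if not response_min <= x <= response_max:
        raise ValueError(f"response {x} outside [{response_min}, {response_max}]")
    return response_min + response_max - x


def score_scale(
    responses: Sequence[float],
    definition: ScaleDefinition,
    missing: str = "error",
    max_imputed: int = 2,
    participant: str | None = None,
) -> float:
    """Score one participant's item vector under a scale definition.

    Reverse-keyed items are reversed, then aggregated by mean (trait
    domains) or sum (stress total).  Missing responses (NaN) raise by
    default; with ``missing="impute"`` up to ``max_imputed`` items are
    replaced by the person's mean over answered (reversed) items.
    """
    x = np.asarray(responses, dtype=float)
    if x.shape != (definition.item_count,):
        raise ValueError(
            f"{definition.name}: expected {definition.item_count} items, got {x.shape}"
        )
    who = f" (participant {participant})" if participant else ""
    answered = ~np.isnan(x)
    bad = answered & ((x < definition.response_min) | (x > definition.response_max))
    if np.any(bad):
        idx = int(np.flatnonzero(bad)[0]) + 1
        raise ValueError(f"{definition.name}: item {idx} out of range{who}")
    if not np.all(answered):
        n_miss = int(np.sum(~answered))
        if missing == "error":
            idx = int(np.flatnonzero(~answered)[0]) + 1
            raise ValueError(f"{definition.name}: item {idx} missing{who}")
        if missing != "impute" or n_miss > max_imputed:
            raise ValueError(f"{definition.name}: {n_miss} missing items exceed policy{who}")

    rev = np.array(sorted(definition.reverse_keyed_items), dtype=int) - 1
    x = x.copy()
    x[rev] = definition.response_min + definition.response_max - x[rev]
    if not np.all(answered):
        x[~answered] = np.nanmean(x)
    return float(np.mean(x)) if definition.aggregation == "mean" else float(np.sum(x))


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha, k/(k−1)·(1 − Σ item variances / total variance).

    ``items`` is a participants × items matrix with reverse-keyed items
    already reversed; sample (n−1) variances throughout.  Returns NaN when
    the total-score variance is zero (alpha undefined).
    """
    m = np.asarray(items, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2 or m.shape[0] < 3:
        raise ValueError("alpha needs >= 3 participants and >= 2 items")
    k = m.shape[1]
    item_var = m.var(axis=0, ddof=1).sum()
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return math.nan
    return k / (k - 1) * (1 - item_var / total_var)


# --- descriptives and correlations -----------------------------------------


@dataclass(frozen=True)
class DescriptiveStats:
    """Mean, sample SD, adjusted skewness (G1) and excess kurtosis (G2)."""

    mean: float
    sd: float
    skewness: float
    kurtosis: float


def descriptives(x: Sequence[float]) -> DescriptiveStats:
    """Sample descriptives with the adjusted (bias-corrected) G1/G2 moments.

    Skewness needs n >= 3 and kurtosis n >= 4; a constant vector has SD 0
    with shape statistics undefined (NaN).
    """
    v = np.asarray(x, dtype=float)
    v = v[~np.isnan(v)]
    n = v.size
    if n < 2:
        raise ValueError("descriptives need at least 2 observations")
    sd = float(np.std(v, ddof=1))
    skew = math.nan
    kurt = math.nan
    if sd > 0:
        if n >= 3:
            skew = float(stats.skew(v, bias=False))
        if n >= 4:
            kurt = float(stats.kurtosis(v, fisher=True, bias=False))
    return DescriptiveStats(float(np.mean(v)), sd, skew, kurt)


class PearsonResult(NamedTuple):
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


def pearson_matrix(columns: pd.DataFrame) -> PearsonResult:
    """Pairwise-complete Pearson correlations with two-tailed p values.

    p follows from t = r·sqrt(n−2)/sqrt(1−r²) on n−2 degrees of freedom.
    Zero-variance pairs are flagged NaN.
    """
    names = list(columns.columns)
    k = len(names)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    data = columns.to_numpy(dtype=float)
    for i in range(k):
        n[i, i] = np.sum(~np.isnan(data[:, i]))
        for j in range(i + 1, k):
            ok = ~np.isnan(data[:, i]) & ~np.isnan(data[:, j])
            m = int(ok.sum())
            n[i, j] = n[j, i] = m
            if m < 3 or np.std(data[ok, i]) == 0 or np.std(data[ok, j]) == 0:
                r[i, j] = r[j, i] = p[i, j] = p[j, i] = math.nan
                continue
            rr, pp = stats.pearsonr(data[ok, i], data[ok, j])
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    mk = lambda a: pd.DataFrame(a, index=names, columns=names)
    return PearsonResult(mk(r), mk(p), mk(n))


# --- participant-level pipeline ---------------------------------------------


def score_participants(items: pd.DataFrame, missing: str = "error") -> pd.DataFrame:
    """Score an items CSV frame into per-participant scale scores.

    Expects columns ``participant_id, bfi_1..bfi_60, pss_1..pss_14,
    subjective_blink``.  Returns one row per participant with the five
    BFI-2 domain means (1-5), the PSS-14 total (0-56) and the subjective
    blink rating (1-7) passed through.
    """
    bfi_cols = [f"bfi_{i}" for i in range(1, 61)]
    pss_cols = [f"pss_{i}" for i in range(1, 15)]
    required = ["participant_id", *bfi_cols, *pss_cols]
    missing_cols = [c for c in required if c not in items.columns]
    if missing_cols:
        raise ValueError(f"items frame missing columns: {missing_cols[:5]}...")

    rows = []
    for _, row in items.iterrows():
        pid = row["participant_id"]
        rec = {"participant_id": pid}
        for domain, item_nums in BFI2_ITEM_MAP.items():
            vec = [row[f"bfi_{abs(i)}"] for i in item_nums]
            rec[domain] = score_scale(vec, BFI2_DOMAINS[domain], missing=missing,
                                      participant=str(pid))
        rec["pss14_total"] = score_scale(
            [row[c] for c in pss_cols], PSS14, missing=missing, participant=str(pid)
        )
        if "subjective_blink" in items.columns:
            sb = row["subjective_blink"]
            if not (np.isnan(sb) or 1 <= sb <= 7):
                raise ValueError(f"subjective_blink out of 1-7 range (participant {pid})")
            rec["subjective_blink"] = sb
        rows.append(rec)
    return pd.DataFrame(rows)


def summary_table(scores: pd.DataFrame, variables: Iterable[str] | None = None) -> pd.DataFrame:
    """Descriptives + zero-order correlation table over the score columns."""
    cols = list(variables) if variables is not None else [
        c for c in scores.columns if c != "participant_id"
    ]
    res = pearson_matrix(scores[cols])
    out = res.r.copy()
    desc = {c: descriptives(scores[c]) for c in cols}
    out["M"] = [desc[c].mean for c in cols]
    out["SD"] = [desc[c].sd for c in cols]
    out["Skewness"] = [desc[c].skewness for c in cols]
    out["Kurtosis"] = [desc[c].kurtosis for c in cols]
    return out
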