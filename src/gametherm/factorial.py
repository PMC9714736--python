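"""Aligned rank transform (ART) factorial ANOVA with effect sizes and posthocs.

The ART procedure makes a factorial ANOVA nonparametric while preserving the
ability to test interactions: for each effect (factor A, factor B, their
interaction A×B) the responses are *aligned* — the cell mean is subtracted and
the estimated effect of interest added back using balanced cell-mean algebra —
then midranked, and a standard two-way fixed-effects ANOVA is run on the
ranks, of which only the F test for the target effect is interpreted.  For a
correctly aligned effect the "stripped" F statistics of the two other effects
on the same aligned-ranked data are ≈ 0, which is exposed as a diagnostic.

Effect sizes follow the usual conventions: partial η² = SS_eff/(SS_eff+SS_err)
per effect from the rank ANOVA, and Cohen's d (pooled-SD standardized mean
difference, computed on the raw response scale) per pairwise contrast, with
Bonferroni-adjusted p-values for the family of level pairs.

Only balanced two-factor designs are supported; the alignment algebra assumes
equal cell counts, and unbalanced tables are rejected rather than silently
misaligned.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FactorialDataset",
    "EffectTest",
    "PairwiseContrast",
    "ARTResult",
    "art_align",
    "art_anova",
    "partial_eta_squared",
    "cohens_d",
    "classify_cohens_d",
    "bonferroni_pairwise",
    "spearman_rho",
]

EFFECTS = ("A", "B", "AB")

#: |d| thresholds (Cohen 1988 extended by Sawilowsky 2009); configurable
COHENS_D_SCALE = (
    (0.01, "very small"),
    (0.2, "small"),
    (0.5, "medium"),
    (0.8, "large"),
    (1.2, "very large"),
    (2.0, "huge"),
)


@dataclass
class FactorialDataset:
    """A two-factor response table (factor A = temperature, B = pH).

    Rows carry one response value per biological replicate and cell; the
    constructor records balance and rejects designs with empty cells.
    """

    response: np.ndarray
    a: np.ndarray
    b: np.ndarray
    pair_id: np.ndarray | None = None
    a_name: str = "temperature"
    b_name: str = "ph"

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        self.a = np.asarray(self.a)
        self.b = np.asarray(self.b)
        n = self.response.size
        if self.a.size != n or self.b.size != n:
            raise ValueError("response and factor columns must have equal length")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("responses must be finite")
        self.a_levels = np.unique(self.a)
        self.b_levels = np.unique(self.b)
        if len(self.a_levels) < 1 or len(self.b_levels) < 1:
            raise ValueError("each factor needs at least one level")
        counts = np.zeros((len(self.a_levels), len(self.b_levels)), dtype=int)
        for i, al in enumerate(self.a_levels):
            for j, bl in enumerate(self.b_levels):
                counts[i, j] = int(np.sum((self.a == al) & (self.b == bl)))
        if np.any(counts == 0):
            raise ValueError("empty cells: alignment is undefined")
        self.cell_counts = counts
        self.balanced = bool(np.all(counts == counts.flat[0]))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, response: str, a: str, b: str,
                   pair_id: str | None = None) -> "FactorialDataset":
        return cls(
            response=df[response].to_numpy(dtype=float),
            a=df[a].to_numpy(), b=df[b].to_numpy(),
            pair_id=df[pair_id].to_numpy() if pair_id else None,
            a_name=a, b_name=b,
        )

    @property
    def n(self) -> int:
        return int(self.response.size)

    def _indices(self):
        ai = np.searchsorted(self.a_levels, self.a) if self.a_levels.dtype.kind in "if" \
            else np.array([list(self.a_levels).index(v) for v in self.a])
        bi = np.searchsorted(self.b_levels, self.b) if self.b_levels.dtype.kind in "if" \
            else np.array([list(self.b_levels).index(v) for v in self.b])
        return ai, bi


@dataclass
class EffectTest:
    effect: str
    f: float
    df_num: int
    df_den: int
    p: float
    partial_eta_squared: float
    ss_effect: float
    ss_error: float
    stripped_f: dict[str, float] = field(default_factory=dict)


@dataclass
class PairwiseContrast:
    factor: str
    level_a: object
    level_b: object
    p_raw: float
    p_adjusted: float
    cohens_d: float
    magnitude: str


@dataclass
class ARTResult:
    """Full aligned-rank ANOVA output for a two-factor design."""

    effects: dict[str, EffectTest]
    posthoc: list[PairwiseContrast]
    aligned_sums: dict[str, float]
    n: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, e in self.effects.items():
            rows.append({
                "effect": name, "F": e.f, "df_num": e.df_num, "df_den": e.df_den,
                "p": e.p, "partial_eta_sq": e.partial_eta_squared,
            })
        return pd.DataFrame(rows)


def _cell_mean_components(data: FactorialDataset):
    """Grand mean, marginal means per level, and cell means, per observation."""
    ai, bi = data._indices()
    na, nb = len(data.a_levels), len(data.b_levels)
    y = data.response
    cell_sum = np.zeros((na, nb))
    cell_n = np.zeros((na, nb))
    np.add.at(cell_sum, (ai, bi), y)
    np.add.at(cell_n, (ai, bi), 1.0)
    cell_mean = cell_sum / cell_n
    # marginal means as unweighted means of cell means (balanced => same as raw)
    a_mean = cell_mean.mean(axis=1)
    b_mean = cell_mean.mean(axis=0)
    grand = cell_mean.mean()
    return ai, bi, cell_mean, a_mean, b_mean, grand


def art_align(data: FactorialDataset, effect: str) -> np.ndarray:
    """Aligned responses for one effect of a two-factor design.

    Each response has its cell mean removed (stripping *all* effects) and the
    estimated target effect added back:

    - ``A``:  residual + (Ā_i.. − grand mean)
    - ``B``:  residual + (B̄_.j − grand mean)
    - ``AB``: residual + (cell̄_ij − Ā_i.. − B̄_.j + grand mean)
    """
    if effect not in EFFECTS:
        raise ValueError(f"effect must be one of {EFFECTS}")
    ai, bi, cell_mean, a_mean, b_mean, grand = _cell_mean_components(data)
    resid = data.response - cell_mean[ai, bi]
    if effect == "A":
        est = a_mean[ai] - grand
    elif effect == "B":
        est = b_mean[bi] - grand
    else:
        est = cell_mean[ai, bi] - a_mean[ai] - b_mean[bi] + grand
    return resid + est


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _twoway_anova_ss(y: np.ndarray, data: FactorialDataset):
    """Balanced two-way fixed-effects sums of squares for response ``y``."""
    ai, bi = data._indices()
    na, nb = len(data.a_levels), len(data.b_levels)
    cell_sum = np.zeros((na, nb))
    cell_n = np.zeros((na, nb))
    np.add.at(cell_sum, (ai, bi), y)
    np.add.at(cell_n, (ai, bi), 1.0)
    cell_mean = cell_sum / cell_n
    a_mean = cell_mean.mean(axis=1)
    b_mean = cell_mean.mean(axis=0)
    grand = cell_mean.mean()
    npc = cell_n.flat[0]
    ss_a = npc * nb * float(np.sum((a_mean - grand) ** 2))
    ss_b = npc * na * float(np.sum((b_mean - grand) ** 2))
    inter = cell_mean - a_mean[:, None] - b_mean[None, :] + grand
    ss_ab = npc * float(np.sum(inter**2))
    ss_err = float(np.sum((y - cell_mean[ai, bi]) ** 2))
    df = {
        "A": na - 1,
        "B": nb - 1,
        "AB": (na - 1) * (nb - 1),
        "error": data.n - na * nb,
    }
    return {"A": ss_a, "B": ss_b, "AB": ss_ab, "error": ss_err}, df


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """Partial η² = SS_effect / (SS_effect + SS_error)."""
    if ss_effect < 0 or ss_error < 0:
        raise ValueError("sums of squares must be non-negative")
    if ss_effect == 0 and ss_error == 0:
        raise ValueError("partial η² undefined when both sums of squares are zero")
    return ss_effect / (ss_effect + ss_error)


def _effect_f(y_ranked: np.ndarray, data: FactorialDataset, effect: str) -> EffectTest:
    ss, df = _twoway_anova_ss(y_ranked, data)
    dfe = df["error"]
    if dfe < 1:
        raise ValueError("fewer than 1 residual degree of freedom")
    total = ss["error"] + sum(ss[e] for e in EFFECTS)
    if total <= 1e-12 * data.n:
        # fully tied ranks (e.g. a noiseless null effect): no variation at all
        return EffectTest(effect=effect, f=0.0, df_num=df[effect], df_den=dfe,
                          p=1.0, partial_eta_squared=0.0, ss_effect=0.0,
                          ss_error=0.0, stripped_f={})
    ms_err = ss["error"] / dfe
    stripped = {}
    for other in EFFECTS:
        if other == effect or df[other] == 0:
            continue
        stripped[other] = (ss[other] / df[other]) / ms_err if ms_err > 0 else 0.0
    dfn = df[effect]
    if dfn == 0:
        raise ValueError(f"effect {effect} has zero degrees of freedom in this design")
    f = (ss[effect] / dfn) / ms_err if ms_err > 0 else math.inf
    p = float(stats.f.sf(f, dfn, dfe)) if math.isfinite(f) else 0.0
    return EffectTest(
        effect=effect, f=float(f), df_num=dfn, df_den=dfe, p=p,
        partial_eta_squared=partial_eta_squared(ss[effect], ss["error"]),
        ss_effect=ss[effect], ss_error=ss["error"], stripped_f=stripped,
    )


def art_anova(data: FactorialDataset, posthoc: bool = True) -> ARTResult:
    """Aligned-rank-transform two-way ANOVA.

    For each estimable effect: align, midrank, and run the balanced two-way
    ANOVA on the ranks, reporting the target effect's F, df, p, and partial
    η², plus the stripped-effect F diagnostics.  Designs where a factor has a
    single level reduce gracefully — only the estimable effects are tested
    (and the target F then equals a one-way ANOVA on ranks of the raw data).
    """
    if not data.balanced:
        raise ValueError("art_anova requires a balanced design")
    na, nb = len(data.a_levels), len(data.b_levels)
    if data.n - na * nb < 1:
        raise ValueError("no residual degrees of freedom")
    effects: dict[str, EffectTest] = {}
    aligned_sums: dict[str, float] = {}
    for effect in EFFECTS:
        dfn = {"A": na - 1, "B": nb - 1, "AB": (na - 1) * (nb - 1)}[effect]
        aligned = art_align(data, effect)
        aligned_sums[effect] = float(aligned.sum())
        if dfn == 0:
            continue
        ranked = _midrank(aligned)
        effects[effect] = _effect_f(ranked, data, effect)
    contrasts: list[PairwiseContrast] = []
    if posthoc:
        if na > 1:
            contrasts += bonferroni_pairwise(data, "A")
        if nb > 1:
            contrasts += bonferroni_pairwise(data, "B")
    return ARTResult(effects=effects, posthoc=contrasts,
                     aligned_sums=aligned_sums, n=data.n)


def cohens_d(group_a, group_b) -> float:
    """Cohen's d with the pooled standard deviation."""
    xa = np.asarray(group_a, dtype=float)
    xb = np.asarray(group_b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = xa.var(ddof=1), xb.var(ddof=1)
    pooled = ((xa.size - 1) * va + (xb.size - 1) * vb) / (xa.size + xb.size - 2)
    if pooled <= 0:
        raise ValueError("pooled standard deviation is zero")
    return float((xa.mean() - xb.mean()) / math.sqrt(pooled))


def classify_cohens_d(d: float, scale=COHENS_D_SCALE) -> str:
    """Verbal magnitude label for |d| on the Cohen/Sawilowsky scale."""
    mag = abs(d)
    label = "negligible"
    for cut, name in scale:
        if mag >= cut:
            label = name
    return label


def bonferroni_pairwise(data: FactorialDataset, factor: str) -> list[PairwiseContrast]:
    """All pairwise level contrasts for one factor.

    Raw p-values are model-based t contrasts of marginal means on the
    ART-aligned ranks for that factor: the standard error uses the MS_error
    and error df of the two-way rank ANOVA (the estimated-marginal-means
    construction usual after ART), not a two-sample test, so the error term
    matches the omnibus F.  The Bonferroni adjustment multiplies by the
    number of pairs and caps at 1.  Cohen's d is reported on the raw
    response scale, matching common reporting practice.
    """
    if factor not in ("A", "B"):
        raise ValueError("factor must be 'A' or 'B'")
    levels = data.a_levels if factor == "A" else data.b_levels
    labels = data.a if factor == "A" else data.b
    if len(levels) < 2:
        raise ValueError("pairwise contrasts need at least 2 levels")
    aligned = art_align(data, factor)
    ranked = _midrank(aligned)
    ss, df = _twoway_anova_ss(ranked, data)
    dfe = df["error"]
    if dfe < 1:
        raise ValueError("fewer than 1 residual degree of freedom")
    ms_err = ss["error"] / dfe
    pairs = list(itertools.combinations(levels, 2))
    m = len(pairs)
    out = []
    for la, lb in pairs:
        ia, ib = labels == la, labels == lb
        n_a, n_b = int(ia.sum()), int(ib.sum())
        diff = ranked[ia].mean() - ranked[ib].mean()
        se = math.sqrt(ms_err * (1.0 / n_a + 1.0 / n_b)) if ms_err > 0 else 0.0
        if se > 0:
            tstat = diff / se
            p_raw = 2.0 * float(stats.t.sf(abs(tstat), dfe))
        else:
            p_raw = 1.0 if diff == 0 else 0.0
        d = cohens_d(data.response[ia], data.response[ib])
        out.append(PairwiseContrast(
            factor=factor, level_a=la, level_b=lb,
            p_raw=float(p_raw), p_adjusted=min(1.0, m * float(p_raw)),
            cohens_d=d, magnitude=classify_cohens_d(d),
        ))
    return out


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman's rank correlation with the large-sample t approximation.

    ρ is the Pearson correlation of midranks; the p-value uses
    t = ρ·sqrt((n−2)/(1−ρ²)) on n−2 degrees of freedom (two-sided), the
    standard approximation for n ≳ 10.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with at least 3 values")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("Spearman correlation undefined for constant input")
    rx, ry = _midrank(x), _midrank(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(np.sum(rx * ry) / math.sqrt(np.sum(rx**2) * np.sum(ry**2)))
    n = x.size
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return rho, min(p, 1.0)
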