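"""Inferential quantities from posterior draws.

The reporting conventions: point estimate = posterior mean (median also
emitted), uncertainty = 95% and 50% highest posterior density intervals
(HPDI = shortest contiguous interval containing the mass), and direction =
probability of direction (pd, share of draws on the predicted side).
Evidence labels: "evidence" when the 95% HPDI excludes zero, "weak" when it
overlaps zero but pd > 0.90, "none" otherwise.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .dhglm import PosteriorDraws

__all__ = [
    "hpdi",
    "prob_direction",
    "classify_evidence",
    "SummaryRow",
    "VarianceContrast",
    "habitat_variance_contrast",
    "back_transform_dispersion",
    "summarize_model",
    "plot_contrast",
]


def hpdi(draws, prob: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval of the sorted draws containing
    ceil(prob * n) draws. Ties between equally short windows break towards
    the lower interval."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("hpdi: empty draws")
    if not 0.0 < prob < 1.0:
        raise ValueError("hpdi: prob must be in (0, 1)")
    m = int(math.ceil(prob * n))
    m = max(m, 1)
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin takes the first (lowest) minimum
    return float(x[i]), float(x[i + m - 1])


def prob_direction(draws, predicted_sign: str = "positive") -> float:
    """Proportion of draws on the predicted side of zero.

    Draws exactly at zero count half towards each side, so
    pd(positive) + pd(negative) = 1 always.
    """
    x = np.asarray(draws, dtype=float)
    if x.size == 0:
        raise ValueError("prob_direction: empty draws")
    if predicted_sign not in ("positive", "negative"):
        raise ValueError("predicted_sign must be 'positive' or 'negative'")
    n_pos = float(np.sum(x > 0)) + 0.5 * float(np.sum(x == 0))
    pd_pos = n_pos / x.size
    return pd_pos if predicted_sign == "positive" else 1.0 - pd_pos


class Evidence(str, enum.Enum):
    EVIDENCE = "evidence"
    WEAK = "weak"
    NONE = "none"


def classify_evidence(draws, predicted_sign: str = "positive") -> Evidence:
    """Evidence when the 95% HPDI excludes zero; weak when pd > 0.90."""
    lo, hi = hpdi(draws, 0.95)
    if lo > 0 or hi < 0:
        return Evidence.EVIDENCE
    if prob_direction(draws, predicted_sign) > 0.90:
        return Evidence.WEAK
    return Evidence.NONE


@dataclass
class SummaryRow:
    term: str
    part: str  # mean | dispersion
    kind: str  # fixed | sd | variance | correlation
    estimate: float
    median: float
    hpdi95: tuple[float, float]
    hpdi50: tuple[float, float]
    pd: float
    evidence: str

    def as_dict(self) -> dict:
        return {
            "term": self.term,
            "part": self.part,
            "kind": self.kind,
            "estimate": self.estimate,
            "median": self.median,
            "hpdi95_lo": self.hpdi95[0],
            "hpdi95_hi": self.hpdi95[1],
            "hpdi50_lo": self.hpdi50[0],
            "hpdi50_hi": self.hpdi50[1],
            "pd": self.pd,
            "evidence": self.evidence,
        }


def _row(term, part, kind, draws, predicted_sign="positive", flag_rule="fixed") -> SummaryRow:
    x = np.asarray(draws, dtype=float)
    h95 = hpdi(x, 0.95)
    h50 = hpdi(x, 0.50)
    pd = prob_direction(x, predicted_sign)
    if flag_rule == "fixed":
        ev = classify_evidence(x, predicted_sign).value
    else:  # random effects: flagged when the 95% HPDI sits above 0.001
        ev = Evidence.EVIDENCE.value if h95[0] > 0.001 else Evidence.NONE.value
    return SummaryRow(term, part, kind, float(x.mean()), float(np.median(x)), h95, h50, pd, ev)


@dataclass
class VarianceContrast:
    """Urban-vs-forest among-cluster variance contrast (parameters 1 and 3).

    ``level`` is "cluster_mean" (parameter 1, mean part) or
    "cluster_dispersion" (parameter 3, dispersion part). All arrays are
    aligned draw-by-draw; variances are SD^2 per draw.
    """

    level: str
    var_urban: np.ndarray
    var_forest: np.ndarray
    diff: np.ndarray  # urban - forest
    ratio: np.ndarray  # urban / forest
    pd: float
    hpdi95_diff: tuple[float, float]
    evidence: str


def habitat_variance_contrast(
    draws: PosteriorDraws, level: str = "cluster_mean", predicted_sign: str = "positive"
) -> VarianceContrast:
    """Per-draw urban/forest variance difference at the requested level.

    Requires a categorical-mode fit (habitat-specific cluster variances);
    an ISA-mode fit has a single pooled cluster variance and raises.
    """
    if level == "cluster_mean":
        base = "sd_cluster"
    elif level == "cluster_dispersion":
        base = "sd_disp_cluster"
    else:
        raise ValueError("level must be 'cluster_mean' or 'cluster_dispersion'")
    try:
        sd_u = draws.get(f"{base}_urban")
        sd_f = draws.get(f"{base}_forest")
    except KeyError as exc:
        raise ValueError(
            "habitat-specific cluster variances are only available from a "
            "categorical-mode fit (ISA-mode fits pool clusters)"
        ) from exc
    var_u, var_f = sd_u**2, sd_f**2
    diff = var_u - var_f
    with np.errstate(divide="ignore"):
        ratio = var_u / var_f
    return VarianceContrast(
        level=level,
        var_urban=var_u,
        var_forest=var_f,
        diff=diff,
        ratio=ratio,
        pd=prob_direction(diff, predicted_sign),
        hpdi95_diff=hpdi(diff, 0.95),
        evidence=classify_evidence(diff, predicted_sign).value,
    )


def back_transform_dispersion(
    gamma_hab, baseline_log_sd=0.0, trait_sd: float = 1.0
) -> tuple[float, float, float]:
    """Back-transform a log-SD habitat coefficient to interpretable units.

    Returns (percent increase in residual SD in urban habitats,
    forest residual SD, urban residual SD), the latter two in original trait
    units when ``trait_sd`` (the SD used for Z-scoring) is given. Accepts a
    scalar coefficient or posterior draws (then means of the transformed
    draws are returned for the SDs and the mean coefficient drives the
    percentage).
    """
    g = float(np.mean(gamma_hab))
    b = np.asarray(baseline_log_sd, dtype=float)
    pct = 100.0 * (math.exp(g) - 1.0)
    sd_forest = float(np.mean(np.exp(b))) * trait_sd
    sd_urban = float(np.mean(np.exp(b + g))) * trait_sd
    return pct, sd_forest, sd_urban


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (matches conventional table formatting)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


#: predicted directions for habitat-related terms (urban > forest)
_PREDICTED_POSITIVE_PREFIXES = ("b_disp[habitat_urban]", "b_disp[isa_")


def summarize_model(draws: PosteriorDraws) -> list[SummaryRow]:
    """One row per fixed effect, random-effect SD, variance and correlation.

    Fixed effects and correlations carry the HPDI-excludes-zero evidence
    flag; random-effect rows use the HPDI-above-0.001 rule. Variances are
    emitted alongside SDs since the two scales are both used in reporting.
    """
    mean_names = draws.meta.get("mean_names") or []
    disp_names = draws.meta.get("disp_names") or []
    rows: list[SummaryRow] = []
    for nm in mean_names:
        key = f"b_mean[{nm}]"
        rows.append(_row(nm, "mean", "fixed", draws.get(key)))
    for nm in disp_names:
        key = f"b_disp[{nm}]"
        rows.append(_row(nm, "dispersion", "fixed", draws.get(key)))
    for name in draws.main_names():
        if name.startswith("sd_"):
            part = "dispersion" if name.startswith("sd_disp") else "mean"
            x = draws.get(name)
            rows.append(_row(name, part, "sd", x, flag_rule="random"))
            rows.append(_row(name.replace("sd_", "var_", 1), part, "variance", x**2, flag_rule="random"))
        elif name.startswith("r_"):
            part = "mean_dispersion"
            rows.append(_row(name, part, "correlation", draws.get(name)))
    return rows


def plot_contrast(contrasts: list[VarianceContrast], path=None):
    """Forest/urban posterior-interval plot for the variance contrasts."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.9 * len(contrasts) + 1.5))
    yticks, ylabels = [], []
    for i, c in enumerate(contrasts):
        for j, (label, x, colour) in enumerate(
            (("forest", c.var_forest, "forestgreen"), ("urban", c.var_urban, "steelblue"))
        ):
            ypos = 2 * i + j
            lo95, hi95 = hpdi(x, 0.95)
            lo50, hi50 = hpdi(x, 0.50)
            ax.plot([lo95, hi95], [ypos, ypos], color=colour, lw=1)
            ax.plot([lo50, hi50], [ypos, ypos], color=colour, lw=3)
            ax.plot([np.mean(x)], [ypos], "o", color=colour)
            yticks.append(ypos)
            ylabels.append(f"{c.level} {label}")
    ax.set_yticks(yticks)
    ax.set_yticklabels(ylabels)
    ax.set_xlabel("among-cluster variance")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
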