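"""Null distributions, empirical p-values and the full report.

The subject sequence is compared against ``r`` synonymous shuffles.  For
every motif X the report carries, following the established key naming:

* ``observedX``, ``repTr_observedX``, ``repTrFrac_observedX`` — the
  subject's motif count, replacement transitions and their ratio;
* ``expectedX`` / ``expectedSdX`` (and the ``repTr_`` / ``repTrFrac_``
  variants) — mean and standard deviation of the null distribution;
* ``belowX``, ``repTr_belowX``, ``repTrFrac_belowX`` — the fraction of
  null replicates strictly below the subject, an empirical estimate of
  the under-representation p-value (over-representation reads off the
  upper tail, p > 1 - q);

and for every motif pair (X, Y):

* ``corXxY``, ``corRepTrXxY``, ``corRepTrFracXxY`` — Pearson correlation
  of the replicate-level metric vectors;
* ``pXcondY``, ``pXcondRepTrY``, ``pXcondRepTrFracY`` — lower-tail
  p-value of X's observed metric under the bivariate-normal conditional
  law given Y's observed metric, which corrects a motif's apparent
  representation for a confounding motif (e.g. an APOBEC motif
  conditional on CpG content).

``BH_below*`` keys add Benjamini–Hochberg-adjusted versions of the
univariate p-values across motifs; they are a convenience beyond the
core metric set.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .codons import CodingSequence
from .motifs import MotifSpec, default_motif_set, motif_metrics
from .shuffle import ShuffleConfig, shuffle_batch

logger = logging.getLogger(__name__)

_FAMILIES = ("counts", "repTr", "repTrFrac")


# ---------------------------------------------------------------------------
# null distribution


@dataclass
class NullDistribution:
    """Replicate-level metric vectors per motif.

    ``counts`` and ``rep_tr`` are integer-valued arrays of length ``r``;
    ``rep_tr_frac`` carries NaN where a replicate had zero motif
    occurrences (a 0/0 fraction carries no information and is dropped
    from downstream summaries rather than imputed).
    """

    motifs: list[MotifSpec]
    counts: dict[str, np.ndarray]
    rep_tr: dict[str, np.ndarray]
    rep_tr_frac: dict[str, np.ndarray]
    replicates: int

    def family(self, name: str) -> dict[str, np.ndarray]:
        return {
            "counts": self.counts,
            "repTr": self.rep_tr,
            "repTrFrac": self.rep_tr_frac,
        }[name]


def build_null(
    seq: CodingSequence,
    cfg: ShuffleConfig,
    motifs: list[MotifSpec] | None = None,
) -> NullDistribution:
    """Shuffle ``seq`` ``cfg.replicates`` times and measure every motif."""
    motifs = list(motifs) if motifs is not None else default_motif_set()
    rng = np.random.default_rng(cfg.seed)
    replicates = shuffle_batch(
        seq, cfg.method, cfg.replicates, rng,
        gc3_include_fixed=cfg.gc3_include_fixed,
        freeze_stops=cfg.freeze_stops,
    )
    counts: dict[str, np.ndarray] = {}
    rep_tr: dict[str, np.ndarray] = {}
    frac: dict[str, np.ndarray] = {}
    for m in motifs:
        cvec = np.empty(cfg.replicates, dtype=np.int64)
        tvec = np.empty(cfg.replicates, dtype=np.int64)
        for j, s in enumerate(replicates):
            met = motif_metrics(s, m)
            cvec[j] = met.motif_count
            tvec[j] = met.replacement_transitions
        fvec = np.where(cvec > 0, tvec / np.maximum(cvec, 1), np.nan)
        n_missing = int(np.isnan(fvec).sum())
        if n_missing:
            logger.info(
                "motif %s: %d/%d replicates had zero occurrences; their "
                "fractions are treated as missing", m.name, n_missing,
                cfg.replicates,
            )
        counts[m.name] = cvec
        rep_tr[m.name] = tvec
        frac[m.name] = fvec
    return NullDistribution(motifs, counts, rep_tr, frac, cfg.replicates)


# ---------------------------------------------------------------------------
# univariate statistics


def empirical_below(
    null_values, observed: float | None, mid_p: bool = False
) -> float | None:
    """Fraction of null values strictly below the observed value.

    This is the empirical under-representation p-value.  ``mid_p=True``
    switches to the mid-p variant ``(#less + #equal/2) / n``, which is
    less anti-conservative for discrete counts; the strict definition is
    the default.  Missing (NaN) null entries are dropped; returns ``None``
    if nothing remains or the observed value is itself missing.
    """
    if observed is None or (isinstance(observed, float) and math.isnan(observed)):
        return None
    v = np.asarray(null_values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        logger.warning("empirical_below: all null entries missing")
        return None
    less = int((v < observed).sum())
    if mid_p:
        return (less + 0.5 * int((v == observed).sum())) / v.size
    return less / v.size


def classify_representation(p: float | None, q: float = 0.05) -> str:
    """``under`` if p < q, ``over`` if p > 1 - q, else ``neutral``."""
    if not 0.0 < q < 0.5:
        raise ValueError("threshold q must lie in (0, 0.5)")
    if p is None:
        return "neutral"
    if p < q:
        return "under"
    if p > 1.0 - q:
        return "over"
    return "neutral"


# ---------------------------------------------------------------------------
# bivariate statistics


def pairwise_correlation(x, y) -> float | None:
    """Pearson correlation with pairwise deletion of missing entries.

    Returns ``None`` when fewer than two complete pairs remain or either
    vector is constant (zero variance).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 2 or np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return None
    return float(sps.pearsonr(x, y).statistic)


def conditional_pvalue(
    obs_x: float,
    obs_y: float,
    mean_x: float,
    mean_y: float,
    sd_x: float,
    sd_y: float,
    rho: float,
) -> float | None:
    """Lower-tail p-value of X under the bivariate-normal conditional law.

    Approximating the joint null of (X, Y) as bivariate normal, X given
    Y = obs_y is normal with mean ``mean_x + rho*(sd_x/sd_y)*(obs_y -
    mean_y)`` and SD ``sd_x*sqrt(1 - rho**2)``.  Degenerate inputs
    (zero SD, |rho| >= 1, missing values) return ``None``.
    """
    vals = (obs_x, obs_y, mean_x, mean_y, sd_x, sd_y, rho)
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in vals):
        return None
    if sd_x <= 0.0 or sd_y <= 0.0 or abs(rho) >= 1.0:
        logger.warning(
            "conditional_pvalue: degenerate parameters (sd_x=%s, sd_y=%s, "
            "rho=%s); reporting missing", sd_x, sd_y, rho,
        )
        return None
    cond_mean = mean_x + rho * (sd_x / sd_y) * (obs_y - mean_y)
    cond_sd = sd_x * math.sqrt(1.0 - rho * rho)
    return float(sps.norm.cdf(obs_x, loc=cond_mean, scale=cond_sd))


# ---------------------------------------------------------------------------
# report


@dataclass
class RepresentationReport:
    """Ordered keyword/value pairs plus run metadata.

    ``values`` maps report keys (``observedTAC``, ``belowTAC``,
    ``corTACxWRC``, ...) to numbers, with ``None`` for metrics that are
    undefined (e.g. the replacement-transition fraction of a motif that
    never occurs).  ``metadata`` records method, replicate count, seed
    and significance threshold.
    """

    values: dict[str, float | int | None] = field(default_factory=dict)
    metadata: dict[str, object] = field(default_factory=dict)

    def __getitem__(self, key: str):
        return self.values[key]

    def __contains__(self, key: str) -> bool:
        return key in self.values

    def keys(self):
        return self.values.keys()

    def to_frame(self) -> pd.DataFrame:
        """Key/value pairs as a two-column DataFrame (missing as NaN)."""
        return pd.DataFrame(
            {"key": list(self.values), "value": [
                np.nan if v is None else v for v in self.values.values()
            ]}
        )

    def classification(self, motif_name: str, family: str = "") -> str:
        """Representation call (under/over/neutral) for one motif."""
        prefix = {"": "below", "repTr": "repTr_below",
                  "repTrFrac": "repTrFrac_below"}[family]
        q = float(self.metadata.get("significance_threshold", 0.05))
        return classify_representation(self.values[prefix + motif_name], q)


def _summaries(vec: np.ndarray) -> tuple[float | None, float | None]:
    v = vec[~np.isnan(vec.astype(float))]
    if v.size == 0:
        return None, None
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return mean, sd


def build_report(
    seq: CodingSequence,
    cfg: ShuffleConfig,
    motifs: list[MotifSpec] | None = None,
    *,
    q: float = 0.05,
    mid_p: bool = False,
    bivariate: bool | list[tuple[str, str]] = True,
    bh_adjust: bool = True,
) -> RepresentationReport:
    """Run the full analysis of one subject sequence.

    Generates the null once, measures the subject and every replicate for
    every motif, and assembles all univariate and bivariate statistics.
    ``bivariate`` may be ``True`` (all unordered pairs), ``False``
    (skip), or an explicit list of motif-name pairs.  Deterministic given
    ``cfg.seed``.
    """
    if not 0.0 < q < 0.5:
        raise ValueError("threshold q must lie in (0, 0.5)")
    motifs = list(motifs) if motifs is not None else default_motif_set()
    names = [m.name for m in motifs]
    if len(set(names)) != len(names):
        raise ValueError("motif names must be unique")
    null = build_null(seq, cfg, motifs)
    observed = {m.name: motif_metrics(seq, m) for m in motifs}

    values: dict[str, float | int | None] = {}
    obs_by_family: dict[str, dict[str, float | None]] = {
        f: {} for f in _FAMILIES
    }
    summ: dict[tuple[str, str], tuple[float | None, float | None]] = {}
    for m in motifs:
        x = m.name
        met = observed[x]
        obs_by_family["counts"][x] = met.motif_count
        obs_by_family["repTr"][x] = met.replacement_transitions
        obs_by_family["repTrFrac"][x] = met.rep_tr_frac
        values[f"observed{x}"] = met.motif_count
        values[f"repTr_observed{x}"] = met.replacement_transitions
        values[f"repTrFrac_observed{x}"] = met.rep_tr_frac
        for fam, prefix in (("counts", ""), ("repTr", "repTr_"),
                            ("repTrFrac", "repTrFrac_")):
            vec = null.family(fam)[x]
            mean, sd = _summaries(vec)
            summ[(fam, x)] = (mean, sd)
            values[f"{prefix}expected{x}"] = mean
            values[f"{prefix}expectedSd{x}"] = sd
            values[f"{prefix}below{x}"] = empirical_below(
                vec, obs_by_family[fam][x], mid_p=mid_p
            )

    if bh_adjust:
        for fam, prefix in (("counts", ""), ("repTr", "repTr_"),
                            ("repTrFrac", "repTrFrac_")):
            raw = [(x, values[f"{prefix}below{x}"]) for x in names]
            present = [(x, p) for x, p in raw if p is not None]
            if present:
                adj = multipletests(
                    [p for _, p in present], method="fdr_bh"
                )[1]
                adjusted = dict(zip((x for x, _ in present), adj))
            else:
                adjusted = {}
            for x in names:
                values[f"BH_{prefix}below{x}"] = (
                    float(adjusted[x]) if x in adjusted else None
                )

    if bivariate:
        if bivariate is True:
            pairs = list(itertools.combinations(names, 2))
        else:
            pairs = [tuple(p) for p in bivariate]
        fam_key = {"counts": "", "repTr": "RepTr", "repTrFrac": "RepTrFrac"}
        rho_cache: dict[tuple[str, str, str], float | None] = {}
        for x, y in pairs:
            for fam in _FAMILIES:
                rho = pairwise_correlation(
                    null.family(fam)[x], null.family(fam)[y]
                )
                rho_cache[(fam, x, y)] = rho
                values[f"cor{fam_key[fam]}{x}x{y}"] = rho
        for x, y in pairs:
            for a, b in ((x, y), (y, x)):
                for fam in _FAMILIES:
                    rho = rho_cache[(fam, x, y)]
                    mean_a, sd_a = summ[(fam, a)]
                    mean_b, sd_b = summ[(fam, b)]
                    p = (
                        None
                        if rho is None or mean_a is None or mean_b is None
                        else conditional_pvalue(
                            obs_by_family[fam][a], obs_by_family[fam][b],
                            mean_a, mean_b, sd_a, sd_b, rho,
                        )
                    )
                    infix = {"counts": "cond", "repTr": "condRepTr",
                             "repTrFrac": "condRepTrFrac"}[fam]
                    values[f"p{a}{infix}{b}"] = p

    metadata: dict[str, object] = {
        "identifier": seq.identifier,
        "sequence_length": len(seq),
        "method": cfg.method,
        "replicates": cfg.replicates,
        "seed": cfg.seed,
        "significance_threshold": q,
        "mid_p": mid_p,
        "freeze_stops": cfg.freeze_stops,
    }
    return RepresentationReport(values=values, metadata=metadata)
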