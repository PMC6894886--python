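"""Species-effect statistics from ISH puncta-bin tables.

Automated ISH quantification reports, per probe and sample, how many cells
carry 1..9 or 10+ fluorescent puncta.  Whether a cell with few puncta is
truly positive for the probed marker is uncertain, so the species contrast
is estimated once per candidate positivity cutoff: for every puncta bin
b = 2..10 cells are binarised into negative (< b puncta) and positive
(>= b), a two-category multinomial (logistic) regression of positivity on
species is fitted with the baseline species (mouse) as reference, and the
per-bin log-odds effects are combined.  The cutoff-selection uncertainty is
propagated by taking the mean species effect across the nine bins divided
by the standard error of that mean as a z-statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

PUNCTA_BINS = [str(b) for b in range(1, 10)] + ["10+"]
_BIN_VALUE = {b: i + 1 for i, b in enumerate(PUNCTA_BINS)}
_P_UNDERFLOW = np.nextafter(0, 1)


@dataclass
class CombinedEffect:
    probe: str
    bin_effects: pd.DataFrame  # bin, effect, se, corrected
    mean_effect: float
    se_mean: float
    z: float
    p: float
    degenerate: bool = False


def _validate_table(t: pd.DataFrame) -> pd.DataFrame:
    required = {"species", "sample", "probe", "puncta_bin", "cell_count", "total_cells"}
    missing = required - set(t.columns)
    if missing:
        raise ValueError(f"puncta table missing columns: {sorted(missing)}")
    t = t.copy()
    bad = ~t.puncta_bin.astype(str).isin(PUNCTA_BINS)
    if bad.any():
        raise ValueError(f"unknown puncta bins: {sorted(t.puncta_bin[bad].unique())}")
    if (t.cell_count < 0).any():
        raise ValueError("cell counts must be non-negative")
    return t


def binarize_at_bin(t: pd.DataFrame, probe: str, b: int) -> pd.DataFrame:
    """Positive/negative cell counts per (species, sample) at cutoff bin b.

    Positive cells have >= b puncta (b in 2..10, with 10 meaning the 10+
    bin); negative = total cells - positive.  Missing bins count as zero.
    """
    if not 2 <= b <= 10:
        raise ValueError("cutoff bin must be in 2..10")
    t = _validate_table(t)
    sub = t[t.probe == probe]
    if sub.empty:
        raise ValueError(f"probe {probe!r} absent from table")
    sub = sub.assign(bin_value=sub.puncta_bin.astype(str).map(_BIN_VALUE))
    grouped = sub.groupby(["species", "sample"])
    pos = grouped.apply(
        lambda g: g.loc[g.bin_value >= b, "cell_count"].sum(), include_groups=False
    )
    total = grouped["total_cells"].first()
    out = pd.DataFrame({"positive": pos, "total": total})
    out["negative"] = out.total - out.positive
    if (out.negative < 0).any():
        raise ValueError("cell counts exceed the per-sample total")
    return out.reset_index()


def species_effect_at_bin(
    binary_counts: pd.DataFrame, baseline: str = "mouse"
) -> tuple[float, float, bool]:
    """Two-category multinomial (logistic) species effect at one cutoff.

    Samples are pooled within species; the effect is the log-odds of
    positivity in the non-baseline species minus the baseline, with Woolf
    SE sqrt(sum 1/n_ij) over the pooled 2x2 table.  Zero cells get an
    add-0.5 continuity correction (flagged).
    """
    species = [s for s in pd.unique(binary_counts.species)]
    if baseline not in species:
        raise ValueError(f"baseline species {baseline!r} not present")
    if len(species) != 2:
        raise ValueError("need exactly 2 species")
    other = next(s for s in species if s != baseline)
    pooled = binary_counts.groupby("species")[["positive", "negative"]].sum()
    cells = np.array(
        [
            pooled.loc[other, "positive"], pooled.loc[other, "negative"],
            pooled.loc[baseline, "positive"], pooled.loc[baseline, "negative"],
        ],
        dtype=float,
    )
    corrected = bool(np.any(cells == 0))
    if corrected:
        cells = cells + 0.5
    a, b_, c, d = cells
    effect = float(np.log((a / b_) / (c / d)))
    se = float(np.sqrt((1 / cells).sum()))
    return effect, se, corrected


def combine_bins(
    effects: pd.DataFrame, probe: str = "", method: str = "dependent"
) -> CombinedEffect:
    """Combine per-bin species effects into one z-statistic.

    The point estimate is the mean effect across bins; the z-statistic is
    that mean over the standard error of the mean.  Because the nine
    binarisations reuse the same cells at nested cutoffs, the per-bin
    effects are strongly positively correlated, so the default
    ``dependent`` standard error combines the between-bin spread (the
    cutoff-selection uncertainty) with the mean per-bin sampling SE under
    the worst-case perfect-dependence assumption:

        SE = sqrt( var(effects)/n  +  mean(se_b)^2 ).

    ``method="sem"`` uses the naive sd(effects)/sqrt(n) instead, which
    treats bins as independent draws; it is strongly anti-conservative on
    nested binarisations and is kept only as the literal reading of the
    combination rule.  A degenerate SE of 0 gives z = +/-inf (p reported
    at the underflow minimum); fewer than 2 finite effects is degenerate.
    """
    finite = effects[np.isfinite(effects.effect)]
    if len(finite) < 2:
        return CombinedEffect(
            probe=probe, bin_effects=effects, mean_effect=np.nan,
            se_mean=np.nan, z=np.nan, p=np.nan, degenerate=True,
        )
    vals = finite.effect.to_numpy(dtype=float)
    n = len(vals)
    mean = float(vals.mean())
    if method == "sem":
        se = float(vals.std(ddof=1) / np.sqrt(n))
    elif method == "dependent":
        se_b = finite.se.to_numpy(dtype=float) if "se" in finite else np.zeros(n)
        se = float(np.sqrt(vals.var(ddof=1) / n + np.mean(se_b) ** 2))
    else:
        raise ValueError(f"unknown combination method {method!r}")
    if se == 0:
        z = np.inf * np.sign(mean) if mean != 0 else 0.0
        p = _P_UNDERFLOW if mean != 0 else 1.0
    else:
        z = mean / se
        p = float(2 * norm.sf(abs(z)))
    return CombinedEffect(
        probe=probe, bin_effects=effects, mean_effect=mean, se_mean=se,
        z=float(z), p=p,
    )


def ish_species_test(
    t: pd.DataFrame, probe: str, baseline: str = "mouse", method: str = "dependent"
) -> CombinedEffect:
    """Full per-probe pipeline: binarise at every cutoff bin 2..10,
    estimate the species effect at each, and combine across bins."""
    rows = []
    for b in range(2, 11):
        counts = binarize_at_bin(t, probe, b)
        effect, se, corrected = species_effect_at_bin(counts, baseline=baseline)
        rows.append({"bin": b, "effect": effect, "se": se, "corrected": corrected})
    return combine_bins(pd.DataFrame(rows), probe=probe, method=method)
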