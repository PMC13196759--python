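"""F1/F2 trait structure and the brain-region volume vs behavior screen.

An F2 intercross whose trait values span the parental range with inflated
variance is the classic signature of a genetically encoded quantitative
trait; :func:`span_analysis` summarizes exactly that.  The volume screen
regresses each atlas region's volume on the photokinesis index across F2
fish (simple linear regression / Pearson correlation) and controls the
screen-wide false discovery rate with Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("photokin")


@dataclass
class SpanSummary:
    """Per-generation moments, F2 span fractions, and variance ratios.

    ``frac_f2_beyond_surface`` is the fraction of F2 fish past the surface
    mean on the side away from the cave mean (and symmetrically for cave).
    Undefined variance ratios (zero-variance denominators, or a missing F1
    group) are None with the reason recorded in ``flags``.
    """

    generations: dict[str, dict]
    frac_f2_beyond_surface: float
    frac_f2_beyond_cave: float
    var_ratio_f2_f1: float | None
    var_ratio_f2_parental: float | None
    f2_min: float
    f2_max: float
    spans_parental_means: bool
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _moments(values: np.ndarray) -> dict:
    return {
        "n": int(values.size),
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)),
        "var": float(values.var(ddof=1)),
    }


def span_analysis(
    surface_pis,
    cave_pis,
    f2_pis,
    f1_pis=None,
) -> SpanSummary:
    """Summarize how the F2 trait distribution spans the parental range."""
    named = {"surface": surface_pis, "cave": cave_pis, "F2": f2_pis}
    if f1_pis is not None:
        named["F1"] = f1_pis
    arrays = {}
    for label, values in named.items():
        if values is None:
            raise ValueError(f"missing required group {label!r}")
        arr = np.asarray(values, dtype=float)
        if arr.size < 3:
            raise ValueError(f"group {label!r} has n < 3")
        arrays[label] = arr

    gens = {label: _moments(arr) for label, arr in arrays.items()}
    flags: list[str] = []
    s_mean, c_mean = gens["surface"]["mean"], gens["cave"]["mean"]
    f2 = arrays["F2"]
    direction = np.sign(s_mean - c_mean)
    if direction == 0:
        flags.append("parental means equal; span fractions use raw > / < comparisons")
        direction = 1.0
    beyond_surface = float(np.mean(direction * f2 > direction * s_mean))
    beyond_cave = float(np.mean(direction * f2 < direction * c_mean))

    f2_var = gens["F2"]["var"]
    ratio_f1 = None
    if "F1" in gens:
        if gens["F1"]["var"] > 0:
            ratio_f1 = f2_var / gens["F1"]["var"]
        else:
            flags.append("F1 variance is zero; F2/F1 variance ratio undefined")
    parental_var = 0.5 * (gens["surface"]["var"] + gens["cave"]["var"])
    if parental_var > 0:
        ratio_parental = f2_var / parental_var
    else:
        ratio_parental = None
        flags.append("parental variance is zero; F2/parental variance ratio undefined")

    lo, hi = min(s_mean, c_mean), max(s_mean, c_mean)
    return SpanSummary(
        generations=gens,
        frac_f2_beyond_surface=beyond_surface,
        frac_f2_beyond_cave=beyond_cave,
        var_ratio_f2_f1=ratio_f1,
        var_ratio_f2_parental=ratio_parental,
        f2_min=float(f2.min()),
        f2_max=float(f2.max()),
        spans_parental_means=bool(f2.min() <= lo and f2.max() >= hi),
        flags=flags,
    )


def volume_pi_screen(
    volumes: pd.DataFrame,
    pis: pd.DataFrame,
    *,
    min_n: int = 10,
    q_level: float = 0.05,
) -> pd.DataFrame:
    """Regress each region's volume on PI across fish; BH-adjust across regions.

    ``volumes`` is long-format (``fish_id, region, volume_um3``); ``pis``
    needs ``fish_id`` and ``pi``.  Fish missing either measurement are
    dropped by the inner join (logged).  Constant-volume regions have an
    undefined correlation; they are flagged in ``note`` and excluded from
    the BH family.  Rows are sorted by q then region name.
    """
    required_v = {"fish_id", "region", "volume_um3"}
    if not required_v.issubset(volumes.columns):
        raise ValueError(f"volumes table needs columns {sorted(required_v)}")
    if not {"fish_id", "pi"}.issubset(pis.columns):
        raise ValueError("pi table needs columns ['fish_id', 'pi']")

    pis = pis[["fish_id", "pi"]].dropna()
    merged = volumes.merge(pis, on="fish_id", how="inner")
    n_dropped = volumes["fish_id"].nunique() - merged["fish_id"].nunique()
    if n_dropped:
        logger.info("volume screen: dropped %d fish without a PI", n_dropped)
    n_fish = merged["fish_id"].nunique()
    if n_fish < min_n:
        raise ValueError(f"only {n_fish} fish after join; need at least {min_n}")
    if merged["region"].nunique() < 1:
        raise ValueError("at least one region is required")

    rows = []
    for region, grp in merged.groupby("region", sort=True):
        vol = grp["volume_um3"].to_numpy(dtype=float)
        pi = grp["pi"].to_numpy(dtype=float)
        if np.ptp(vol) == 0 or np.ptp(pi) == 0:
            rows.append(
                dict(
                    region=region,
                    n=len(grp),
                    r=np.nan,
                    slope=np.nan,
                    intercept=np.nan,
                    p=np.nan,
                    q=np.nan,
                    note="constant input; correlation undefined",
                )
            )
            logger.warning("region %s skipped: constant volume or PI", region)
            continue
        fit = sps.linregress(pi, vol)
        rows.append(
            dict(
                region=region,
                n=len(grp),
                r=float(fit.rvalue),
                slope=float(fit.slope),
                intercept=float(fit.intercept),
                p=float(fit.pvalue),
                q=np.nan,
                note="",
            )
        )
    table = pd.DataFrame(rows)
    ok = table["note"] == ""
    if ok.any():
        table.loc[ok, "q"] = multipletests(
            table.loc[ok, "p"].to_numpy(), alpha=q_level, method="fdr_bh"
        )[1]
    table = table.sort_values(
        ["q", "region"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    return table
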