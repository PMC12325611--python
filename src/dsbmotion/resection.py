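"""Restriction-enzyme qPCR resection assay and HO-cutting calculators.

The assay measures 5'->3' end-resection at a site-specific break: StyI
cannot cleave single-stranded DNA, so once resection has passed a StyI site
the template survives digestion and amplifies across the restriction site.
Comparing digested to mock-digested quantification cycles (dCq) at probe
sites 0.7, 5 and 10 kb from the cut, normalised by the ADH1 control gene
(no StyI dependence), gives the fraction of cells whose resection front has
passed each site:

    x = 2 / ( ( E_RS**dCq_RS / E_ADH1**dCq_ADH1 + 1 ) * f )

with E the primer efficiencies (ideal 2.0) and f the fraction of cells in
which the HO endonuclease has cleaved. Cutting itself is measured with
primers flanking the HO site as a fold change relative to the 0 h control:

    fold_t = 2 ** -(dCt_t - dCt_control_average),   dCt = Cq(HO) - Cq(ADH1).

Replicates are aggregated at the Cq level (mean of triplicate Cq before any
dCq) rather than at the fraction level. x values above 1 — possible with
noisy Cq or an underestimated f — are returned raw with a QC flag, never
clamped, so plots show exactly what the equation yields.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import CONTROL_SITE, HO_SITE, QPCR_SITES


@dataclass(frozen=True)
class EfficiencySet:
    """Per-primer-pair amplification efficiencies, 1 < E <= 2 (ideal 2)."""

    e_rs: dict[str, float] = field(
        default_factory=lambda: {s: 2.0 for s in QPCR_SITES}
    )
    e_adh1: float = 2.0

    def __post_init__(self) -> None:
        for site, e in self.e_rs.items():
            if not (1.0 < e <= 2.0):
                raise ValueError(f"E for {site} must be in (1, 2], got {e}")
        if not (1.0 < self.e_adh1 <= 2.0):
            raise ValueError(f"E_ADH1 must be in (1, 2], got {self.e_adh1}")


@dataclass
class ResectionResult:
    site: str
    timepoint_h: float
    fraction_resected: float  # x; > 1 allowed but flagged
    delta_cq_rs: float
    delta_cq_adh1: float
    f_used: float
    flags: list[str] = field(default_factory=list)


@dataclass
class CuttingResult:
    timepoint_h: float
    fold_increase: float
    delta_ct: float
    delta_ct_control: float
    flags: list[str] = field(default_factory=list)


def delta_cq(
    table: pd.DataFrame, site: str, timepoint: float, sample: str | None = None
) -> float:
    """mean(digest Cq) - mean(mock Cq) for one site and timepoint."""
    sel = (table["site"] == site) & (table["timepoint_h"] == timepoint)
    if sample is not None:
        sel &= table["sample"] == sample
    sub = table[sel]
    means = {}
    for treatment in ("mock", "digest"):
        vals = sub.loc[sub["treatment"] == treatment, "cq"]
        if vals.empty:
            raise ValueError(
                f"missing {treatment} replicates for site={site!r}, "
                f"timepoint={timepoint}" + (f", sample={sample!r}" if sample else "")
            )
        means[treatment] = float(vals.mean())
    return means["digest"] - means["mock"]


def fraction_resected(
    dcq_rs: float,
    dcq_adh1: float,
    eff: EfficiencySet | None = None,
    f: float = 1.0,
    site: str = "RS_0.7kb",
    timepoint_h: float = np.nan,
) -> ResectionResult:
    """Fraction of cells whose resection front has passed the probe site."""
    eff = eff or EfficiencySet()
    if not (0.0 < f <= 1.0):
        raise ValueError(f"cut fraction f must be in (0, 1], got {f}")
    e_rs = eff.e_rs.get(site)
    if e_rs is None:
        raise ValueError(f"no efficiency for site {site!r}")
    ratio = e_rs**dcq_rs / eff.e_adh1**dcq_adh1
    x = 2.0 / ((ratio + 1.0) * f)
    flags = []
    if x > 1.0:
        flags.append("fraction_above_1")
    return ResectionResult(
        site=site,
        timepoint_h=timepoint_h,
        fraction_resected=float(x),
        delta_cq_rs=float(dcq_rs),
        delta_cq_adh1=float(dcq_adh1),
        f_used=float(f),
        flags=flags,
    )


def cutting_fold_increase(
    table: pd.DataFrame,
    timepoint: float,
    control_timepoint: float = 0.0,
    sample: str | None = None,
) -> CuttingResult:
    """Fold change of intact HO-site template vs the 0 h control.

    dCt = Cq(HO site) - Cq(ADH1) per timepoint (undigested template);
    fold = 2 ** -(dCt - dCt_control_average).
    """

    def dct(t: float) -> float:
        sel = table["timepoint_h"] == t
        if sample is not None:
            sel &= table["sample"] == sample
        sub = table[sel & (table["treatment"] == "none")]
        ho = sub.loc[sub["site"] == HO_SITE, "cq"]
        adh = sub.loc[sub["site"] == CONTROL_SITE, "cq"]
        if ho.empty or adh.empty:
            missing = HO_SITE if ho.empty else CONTROL_SITE
            raise ValueError(f"missing {missing} rows at timepoint {t}")
        return float(ho.mean() - adh.mean())

    dct_t = dct(timepoint)
    dct_c = dct(control_timepoint)
    fold = float(2.0 ** -(dct_t - dct_c))
    return CuttingResult(
        timepoint_h=timepoint,
        fold_increase=fold,
        delta_ct=dct_t,
        delta_ct_control=dct_c,
    )


def cut_fraction_from_fold(
    fold_by_timepoint: dict[float, float]
) -> dict[float, tuple[float, list[str]]]:
    """Convert the intact-template fold series into a cut fraction f.

    Convention (this package's, not a published one): with primers flanking
    the cut site on undigested DNA, the fold change relative to 0 h is the
    fraction of template still intact, so f = 1 - fold_remaining. Values are
    clipped into [0, 1] with a flag when noise pushes them outside.
    """
    t0 = min(fold_by_timepoint)
    if not np.isclose(fold_by_timepoint[t0], 1.0, atol=1e-9):
        raise ValueError("fold series must include the control timepoint with fold = 1")
    out = {}
    for t, fold in fold_by_timepoint.items():
        f = 1.0 - fold
        flags = []
        if f < 0.0 or f > 1.0:
            flags.append("clipped")
            f = float(np.clip(f, 0.0, 1.0))
        out[t] = (float(f), flags)
    return out


def resection_timecourse(
    table: pd.DataFrame,
    eff: EfficiencySet | None = None,
    f: float | dict[float, float] = 1.0,
    sites: tuple[str, ...] = QPCR_SITES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-replicate fractions and the across-replicate summary.

    ``table`` may contain several biological replicates (distinct ``sample``
    values), each with triplicate Cq rows. Returns (tidy, summary):
    tidy has one row per sample x site x timepoint with the estimated
    fraction and flags; summary has mean and SEM across biological
    replicates per site x timepoint (SEM reported as NaN with one
    replicate). All replicates must probe the same sites.
    """
    eff = eff or EfficiencySet()
    samples = sorted(table["sample"].unique())
    site_sets = {
        s: frozenset(table.loc[(table["sample"] == s) & table["site"].isin(sites), "site"])
        for s in samples
    }
    if len(set(site_sets.values())) > 1:
        raise ValueError(f"inconsistent site sets across replicates: {site_sets}")

    rows = []
    for s in samples:
        sub = table[table["sample"] == s]
        timepoints = sorted(sub.loc[sub["site"].isin(sites), "timepoint_h"].unique())
        for t in timepoints:
            ft = f[t] if isinstance(f, dict) else f
            dcq_adh1 = delta_cq(sub, CONTROL_SITE, t, sample=s)
            for site in sites:
                if site not in site_sets[s]:
                    continue
                if sub[(sub["site"] == site) & (sub["timepoint_h"] == t)].empty:
                    continue  # site not probed at this timepoint
                dcq_rs = delta_cq(sub, site, t, sample=s)
                res = fraction_resected(
                    dcq_rs, dcq_adh1, eff=eff, f=ft, site=site, timepoint_h=t
                )
                rows.append(
                    {
                        "sample": s,
                        "site": site,
                        "timepoint_h": t,
                        "fraction_resected": res.fraction_resected,
                        "delta_cq_rs": res.delta_cq_rs,
                        "delta_cq_adh1": res.delta_cq_adh1,
                        "f_used": res.f_used,
                        "flags": ";".join(res.flags),
                    }
                )
    tidy = pd.DataFrame(rows)
    grp = tidy.groupby(["site", "timepoint_h"])["fraction_resected"]
    summary = grp.agg(
        mean_x="mean",
        sem_x=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
        n="size",
    ).reset_index()
    return tidy, summary
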