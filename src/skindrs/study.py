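"""End-to-end severity study: inversion, features, and statistics.

`SeverityStudy` is the modelling object: it holds a cohort (measured or
synthetic), a trained inverse model and a chromophore basis, and `fit()`
runs the full analysis — per-site spectral inversion, hemoglobin unmixing
and PWFR extraction, per-group summaries, lesion-vs-uninvolved t-tests, the
correlation tables relating instrument readings, derived features and PASI
subscores, and the configured Fisher comparisons of correlation
coefficients. The result object carries every number the report prints;
rendering never recomputes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .chromophores import ChromophoreBasis, load_chromophore_basis
from .cohort import LESION, UNINVOLVED, Cohort
from .features import extract_site_features
from .inverse import InverseModel, build_property_grid, invert_spectrum, train_inverse
from .stats import compare_correlations, pearson_with_p, two_sample_ttest

__all__ = [
    "SeverityStudy",
    "SeverityStudyResults",
    "FisherSpec",
    "run_study",
    "render_report",
    "DEFAULT_FISHER_SPECS",
]

FEATURES = ["c_o2hb", "c_hhb", "c_thb", "pwfr"]
READINGS = ["corneometer", "mexameter"]
PASI = ["pasi_erythema", "pasi_thickness", "pasi_desquamation"]


@dataclass(frozen=True)
class FisherSpec:
    """One Fisher comparison between two correlation-table cells."""

    name: str
    cell1: str  # correlation_table key "group:x:y"
    cell2: str
    use_magnitudes: bool = False
    tail: str = "one"


#: the three comparisons of the default analysis: which PASI subscore drives
#: PWFR, which hemoglobin species drives rated erythema, and whether
#: thickness and desquamation contribute differently to the Corneometer
DEFAULT_FISHER_SPECS = (
    FisherSpec(
        "pwfr_desquamation_vs_thickness",
        "lesion:pwfr:pasi_desquamation",
        "lesion:pwfr:pasi_thickness",
    ),
    FisherSpec(
        "erythema_hhb_vs_o2hb",
        "lesion:c_hhb:pasi_erythema",
        "lesion:c_o2hb:pasi_erythema",
    ),
    FisherSpec(
        "corneometer_desquamation_vs_thickness",
        "lesion:corneometer:pasi_desquamation",
        "lesion:corneometer:pasi_thickness",
        use_magnitudes=True,
    ),
)

_CORR_LAYOUT: List[tuple] = (
    # barrier-function block (PASI thickness / desquamation vs Corneometer, PWFR)
    [("lesion", x, y) for x in ("corneometer", "pwfr")
     for y in ("pasi_thickness", "pasi_desquamation")]
    # erythema block (PASI erythema vs Mexameter and hemoglobin)
    + [("lesion", x, "pasi_erythema")
       for x in ("mexameter", "c_thb", "c_o2hb", "c_hhb")]
    # instrument cross-validation blocks, per site type
    + [(g, "pwfr", "corneometer") for g in (LESION, UNINVOLVED)]
    + [(g, x, "mexameter") for g in (LESION, UNINVOLVED)
       for x in ("c_thb", "c_o2hb", "c_hhb")]
)


@dataclass
class SeverityStudyResults:
    """Fitted study: summaries, tests, correlations, Fisher comparisons."""

    site_features: pd.DataFrame
    summary_table: pd.DataFrame
    group_tests: pd.DataFrame
    correlation_table: pd.DataFrame
    fisher_comparisons: pd.DataFrame
    excluded_sites: List[dict]
    run_meta: dict

    def correlation_cell(self, key: str) -> pd.Series:
        hit = self.correlation_table[self.correlation_table["cell"] == key]
        if hit.empty:
            raise KeyError(f"no correlation cell {key!r}")
        return hit.iloc[0]

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "site_features": self.site_features.to_dict(orient="list"),
            "summary_table": self.summary_table.to_dict(orient="list"),
            "group_tests": self.group_tests.to_dict(orient="list"),
            "correlation_table": self.correlation_table.to_dict(orient="list"),
            "fisher_comparisons": self.fisher_comparisons.to_dict(orient="list"),
            "excluded_sites": self.excluded_sites,
            "run_meta": self.run_meta,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SeverityStudyResults":
        return cls(
            site_features=pd.DataFrame(payload["site_features"]),
            summary_table=pd.DataFrame(payload["summary_table"]),
            group_tests=pd.DataFrame(payload["group_tests"]),
            correlation_table=pd.DataFrame(payload["correlation_table"]),
            fisher_comparisons=pd.DataFrame(payload["fisher_comparisons"]),
            excluded_sites=payload["excluded_sites"],
            run_meta=payload["run_meta"],
        )

    def summary(self) -> str:
        return render_report(self, "markdown")


class SeverityStudy:
    """Severity analysis model over a paired lesion/uninvolved cohort."""

    def __init__(
        self,
        cohort: Cohort,
        inverse_model: Optional[InverseModel] = None,
        basis: Optional[ChromophoreBasis] = None,
        fisher_specs=DEFAULT_FISHER_SPECS,
    ):
        if len(cohort) == 0:
            raise ValueError("empty cohort")
        self.cohort = cohort
        self.basis = basis if basis is not None else load_chromophore_basis()
        if inverse_model is None:
            inverse_model = train_inverse(build_property_grid(), seed=0)
        self.inverse_model = inverse_model
        self.fisher_specs = tuple(fisher_specs)

    @classmethod
    def from_cohort(cls, cohort: Cohort, **kwargs) -> "SeverityStudy":
        return cls(cohort, **kwargs)

    # -- fitting ------------------------------------------------------------
    def fit(self) -> SeverityStudyResults:
        rows = []
        excluded = []
        for _, rec in self.cohort.table.iterrows():
            subject = int(rec["subject"])
            site = rec["site_type"]
            try:
                optics = invert_spectrum(
                    self.inverse_model, self.cohort.spectrum(subject, site)
                )
                feats = extract_site_features(optics, self.basis)
            except Exception as exc:  # noqa: BLE001 - site-level quarantine
                excluded.append(
                    {"subject": subject, "site_type": site, "reason": str(exc)}
                )
                continue
            row = {
                "subject": subject,
                "site_type": site,
                "c_o2hb": feats.c_o2hb,
                "c_hhb": feats.c_hhb,
                "c_thb": feats.c_thb,
                "pwfr": feats.pwfr,
            }
            for col in READINGS + PASI:
                row[col] = rec[col]
            rows.append(row)
        if not rows:
            raise ValueError("all sites failed inversion")
        site_features = pd.DataFrame(rows)

        summary = self._summaries(site_features)
        tests = self._group_tests(site_features)
        corr = self._correlations(site_features)
        fisher = self._fisher(corr)
        meta = {
            "n_subjects": int(self.cohort.table["subject"].nunique()),
            "seed": self.cohort.config.seed,
            "inverse_kind": self.inverse_model.kind,
            "package_version": _pkg_version,
            "p_values": "unadjusted",
        }
        return SeverityStudyResults(
            site_features=site_features,
            summary_table=summary,
            group_tests=tests,
            correlation_table=corr,
            fisher_comparisons=fisher,
            excluded_sites=excluded,
            run_meta=meta,
        )

    def _summaries(self, sf: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for group, sub in sf.groupby("site_type"):
            for col in FEATURES + READINGS + PASI:
                rows.append(
                    {
                        "site_type": group,
                        "variable": col,
                        "mean": float(sub[col].mean()),
                        "sd": float(sub[col].std(ddof=1)) if len(sub) > 1 else np.nan,
                        "n": int(len(sub)),
                    }
                )
        return pd.DataFrame(rows)

    def _group_tests(self, sf: pd.DataFrame) -> pd.DataFrame:
        lesion = sf[sf["site_type"] == LESION]
        normal = sf[sf["site_type"] == UNINVOLVED]
        rows = []
        for col in FEATURES + READINGS:
            if len(lesion) < 2 or len(normal) < 2:
                rows.append({"variable": col, "t": np.nan, "df": np.nan,
                             "p_value": np.nan})
                continue
            res = two_sample_ttest(lesion[col], normal[col], tails="two")
            rows.append(
                {"variable": col, "t": res.t, "df": res.df, "p_value": res.p_value}
            )
        return pd.DataFrame(rows)

    def _correlations(self, sf: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for group, x, y in _CORR_LAYOUT:
            sub = sf[sf["site_type"] == group]
            key = f"{group}:{x}:{y}"
            if len(sub) < 3:
                rows.append(
                    {"cell": key, "site_type": group, "x": x, "y": y,
                     "r": np.nan, "n": int(len(sub)), "p_value": np.nan,
                     "defined": False}
                )
                continue
            try:
                res = pearson_with_p(sub[x], sub[y])
            except ValueError:
                rows.append(
                    {"cell": key, "site_type": group, "x": x, "y": y,
                     "r": np.nan, "n": int(len(sub)), "p_value": np.nan,
                     "defined": False}
                )
                continue
            rows.append(
                {"cell": key, "site_type": group, "x": x, "y": y,
                 "r": res.r, "n": res.n, "p_value": res.p_value, "defined": True}
            )
        return pd.DataFrame(rows)

    def _fisher(self, corr: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for spec in self.fisher_specs:
            c1 = corr[corr["cell"] == spec.cell1]
            c2 = corr[corr["cell"] == spec.cell2]
            if c1.empty or c2.empty:
                raise ValueError(
                    f"Fisher comparison {spec.name} references missing cells"
                )
            c1, c2 = c1.iloc[0], c2.iloc[0]
            if not (c1["defined"] and c2["defined"]):
                rows.append({"name": spec.name, "cell1": spec.cell1,
                             "cell2": spec.cell2, "z1": np.nan, "z2": np.nan,
                             "z_stat": np.nan, "p_one_tailed": np.nan,
                             "defined": False})
                continue
            cmp = compare_correlations(
                c1["r"], int(c1["n"]), c2["r"], int(c2["n"]),
                tail=spec.tail, use_magnitudes=spec.use_magnitudes,
            )
            rows.append(
                {"name": spec.name, "cell1": spec.cell1, "cell2": spec.cell2,
                 "z1": cmp.z1, "z2": cmp.z2, "z_stat": cmp.z_stat,
                 "p_one_tailed": cmp.p_one_tailed, "defined": True}
            )
        return pd.DataFrame(rows)


def run_study(
    cohort: Cohort,
    inverse: InverseModel,
    basis: ChromophoreBasis,
    fisher_specs=DEFAULT_FISHER_SPECS,
) -> SeverityStudyResults:
    """Functional entry point; equivalent to SeverityStudy(...).fit()."""
    return SeverityStudy(
        cohort, inverse_model=inverse, basis=basis, fisher_specs=fisher_specs
    ).fit()


def render_report(report: SeverityStudyResults, format: str = "markdown") -> str:
    """Serialise a fitted study: lossless JSON or human-readable markdown."""
    if format == "json":
        return json.dumps(report.to_dict(), default=float)
    if format != "markdown":
        raise ValueError(f"unknown format {format!r}")
    lines = ["# DRS severity study report", ""]
    meta = report.run_meta
    lines.append(
        f"n_subjects={meta['n_subjects']}, seed={meta['seed']}, "
        f"inverse={meta['inverse_kind']}, p-values unadjusted"
    )
    if report.excluded_sites:
        lines.append(f"excluded sites: {report.excluded_sites}")
    lines += ["", "## Group summaries (mean / SD)", ""]
    lines.append("| variable | lesion | uninvolved |")
    lines.append("| --- | --- | --- |")
    st = report.summary_table
    for var in st["variable"].unique():
        cells = []
        for group in (LESION, UNINVOLVED):
            row = st[(st["variable"] == var) & (st["site_type"] == group)]
            cells.append(
                f"{row.iloc[0]['mean']:.2f} / {row.iloc[0]['sd']:.2f}"
                if not row.empty else "-"
            )
        lines.append(f"| {var} | {cells[0]} | {cells[1]} |")
    lines += ["", "## Lesion vs uninvolved (Student's t, two-sided)", ""]
    lines.append("| variable | t | df | p |")
    lines.append("| --- | --- | --- | --- |")
    for _, row in report.group_tests.iterrows():
        lines.append(
            f"| {row['variable']} | {row['t']:.3f} | {row['df']:.0f} "
            f"| {row['p_value']:.3g} |"
        )
    lines += ["", "## Correlations (Pearson r, p vs y = constant)", ""]
    lines.append("| site | x | y | r | n | p |")
    lines.append("| --- | --- | --- | --- | --- | --- |")
    for _, row in report.correlation_table.iterrows():
        r = f"{row['r']:.2f}" if row["defined"] else "undefined"
        p = f"{row['p_value']:.3g}" if row["defined"] else "-"
        lines.append(
            f"| {row['site_type']} | {row['x']} | {row['y']} | {r} "
            f"| {row['n']} | {p} |"
        )
    if len(report.fisher_comparisons):
        lines += ["", "## Fisher comparisons of correlation coefficients", ""]
        lines.append("| comparison | z1 | z2 | z | one-tailed p |")
        lines.append("| --- | --- | --- | --- | --- |")
        for _, row in report.fisher_comparisons.iterrows():
            if row["defined"]:
                lines.append(
                    f"| {row['name']} | {row['z1']:.3f} | {row['z2']:.3f} "
                    f"| {row['z_stat']:.3f} | {row['p_one_tailed']:.3f} |"
                )
            else:
                lines.append(f"| {row['name']} | - | - | - | undefined |")
    return "\n".join(lines) + "\n"
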