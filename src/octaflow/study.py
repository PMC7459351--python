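"""Cohort-level analysis: group comparisons and the BP-vs-microvasculature
partial-correlation grid.

The analysis is organized as a model/results pair: :class:`CohortStudy` is
built from a per-patient table (covariates, 1-year BP features, retinal
outcomes) and ``fit()`` returns :class:`CohortStudyResults` carrying the
demographics comparison table, the full partial-correlation grid with its
per-cell n and covariate count, and the exclusion log.  ``run_study`` wraps
the same objects behind file-based inputs and outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bp as bp_mod
from . import quant
from .image import load_angiogram
from .stats import (
    GroupSummary,
    chi2_2x2,
    partial_correlation,
    t_test_from_summaries,
    t_test_raw,
)

BP_PARAMETERS = (
    "sbp_enroll",
    "dbp_enroll",
    "avg_sbp",
    "avg_dbp",
    "max_sbp",
    "max_dbp",
    "sd_sbp",
    "sd_dbp",
    "prop_high_sbp",
)
OUTCOMES = ("svp_density", "dvp_density", "flow_void_area")
COVARIATES = ("age", "male", "dm", "axial_length", "iop")

TABLE1_CONTINUOUS = (
    ("age", "Age, years"),
    ("sbp_enroll", "SBP at enrollment, mmHg"),
    ("dbp_enroll", "DBP at enrollment, mmHg"),
    ("iop", "Intraocular pressure, mmHg"),
    ("axial_length", "Axial length, mm"),
    ("svp_density", "Parafoveal SVP vessel density, %"),
    ("dvp_density", "Parafoveal DVP vessel density, %"),
    ("flow_void_area", "Parafoveal SVP flow void area, mm2"),
    ("faz_area", "Foveal avascular zone size, mm2"),
)
TABLE1_CKD_ONLY = ("avg_sbp", "avg_dbp", "max_sbp", "max_dbp", "sd_sbp", "sd_dbp")


class ReconciliationError(ValueError):
    """Image files and patient table do not cross-reference; lists orphans."""

    def __init__(self, orphans: list[str]):
        self.orphans = orphans
        super().__init__(f"images with no matching patient: {orphans}")


def select_eye(per_eye_quality: dict[str, float]) -> str:
    """Pick the study eye: higher quality score wins, ties go to the right
    eye ('OD'); with one eligible eye that eye is used."""
    if not per_eye_quality:
        raise ValueError("no eligible eye")
    best = max(per_eye_quality.values())
    tied = [e for e, q in per_eye_quality.items() if q == best]
    if len(tied) == 1:
        return tied[0]
    for right in ("OD", "R", "right"):
        if right in tied:
            return right
    return sorted(tied)[0]


@dataclass
class CohortStudy:
    """Case/control study model over a per-patient table.

    Parameters
    ----------
    table
        One row per enrolled patient with a ``group`` column ("CKD" /
        "control"), the five covariates, the retinal outcomes, and — for
        CKD patients — the 1-year BP feature columns.
    t_variant
        "pooled", "welch" or "auto" for the group comparisons.
    min_measurements
        Eligibility floor on the 1-year BP measurement count.
    """

    table: pd.DataFrame
    t_variant: str = "pooled"
    min_measurements: int = bp_mod.MIN_MEASUREMENTS
    covariates: tuple[str, ...] = COVARIATES

    @classmethod
    def from_frames(
        cls,
        cohort: pd.DataFrame,
        bp_visits: pd.DataFrame | None = None,
        **kwargs,
    ) -> "CohortStudy":
        """Assemble the study table from a covariate/outcome table and an
        optional long-format BP visit table (merged on ``patient_id``)."""
        table = cohort.copy()
        if bp_visits is not None:
            series = bp_mod.series_from_frame(bp_visits)
            feats = pd.DataFrame([bp_mod.compute_bp_features(s).as_dict() for s in series])
            feats["patient_id"] = feats["patient_id"].astype(str)
            table["patient_id"] = table["patient_id"].astype(str)
            overlap = [
                c for c in feats.columns if c != "patient_id" and c in table.columns
            ]
            table = table.drop(columns=overlap).merge(feats, on="patient_id", how="left")
        return cls(table=table, **kwargs)

    def fit(self) -> "CohortStudyResults":
        df = self.table
        ckd_all = df[df["group"] == "CKD"]
        control = df[df["group"] == "control"]

        exclusions = []
        if "n_measurements" in ckd_all.columns:
            nm = ckd_all["n_measurements"].fillna(0)
            for _, row in ckd_all[nm < self.min_measurements].iterrows():
                exclusions.append(
                    {
                        "patient_id": row["patient_id"],
                        "reason_code": "bp_measurements_lt_3",
                    }
                )
            ckd = ckd_all[nm >= self.min_measurements]
        else:
            ckd = ckd_all

        table1 = self._table1(control, ckd)
        table2, dropped = self._table2(ckd)
        return CohortStudyResults(
            model=self,
            table1=table1,
            table2=table2,
            n_enrolled=len(df),
            n_analyzed=len(ckd) + len(control),
            exclusions=pd.DataFrame(exclusions, columns=["patient_id", "reason_code"]),
            n_dropped_missing=dropped,
        )

    def _table1(self, control: pd.DataFrame, ckd: pd.DataFrame) -> pd.DataFrame:
        rows = []
        # sex: chi2 on the 2x2 female/male x group table
        if "male" in ckd.columns and len(control) and len(ckd):
            tab = np.array(
                [
                    [(control["male"] == 0).sum(), (ckd["male"] == 0).sum()],
                    [(control["male"] == 1).sum(), (ckd["male"] == 1).sum()],
                ]
            )
            res = chi2_2x2(tab)
            rows.append(
                {
                    "variable": "Sex (female/male)",
                    "control": f"{tab[0,0]}/{tab[1,0]}",
                    "ckd": f"{tab[0,1]}/{tab[1,1]}",
                    "p_value": res.p_value,
                    "method": res.method.value,
                }
            )
        for col, label in TABLE1_CONTINUOUS:
            if col not in ckd.columns:
                continue
            a = control[col].dropna().to_numpy() if col in control.columns else np.array([])
            b = ckd[col].dropna().to_numpy()
            if len(a) >= 2 and len(b) >= 2:
                res = t_test_raw(a, b, variant=self.t_variant)
                rows.append(
                    {
                        "variable": label,
                        "control": f"{a.mean():.3g} ± {a.std(ddof=1):.3g}",
                        "ckd": f"{b.mean():.3g} ± {b.std(ddof=1):.3g}",
                        "p_value": res.p_value,
                        "method": res.method.value,
                    }
                )
        for col in TABLE1_CKD_ONLY:
            if col not in ckd.columns:
                continue
            b = ckd[col].dropna().to_numpy()
            if len(b) >= 2:
                rows.append(
                    {
                        "variable": f"{col} (1-year, CKD only)",
                        "control": "-",
                        "ckd": f"{b.mean():.3g} ± {b.std(ddof=1):.3g}",
                        "p_value": np.nan,
                        "method": "summary",
                    }
                )
        return pd.DataFrame(rows)

    def _table2(self, ckd: pd.DataFrame) -> tuple[pd.DataFrame, int]:
        rows = []
        dropped_total = 0
        covs = list(self.covariates)
        for param in BP_PARAMETERS:
            if param not in ckd.columns:
                continue
            for outcome in OUTCOMES:
                if outcome not in ckd.columns:
                    continue
                sub = ckd[[param, outcome, *covs]].dropna()
                dropped_total += len(ckd) - len(sub)
                res = partial_correlation(
                    sub[param].to_numpy(),
                    sub[outcome].to_numpy(),
                    sub[covs].to_numpy(),
                )
                rows.append(
                    {
                        "bp_parameter": param,
                        "outcome": outcome,
                        "coefficient": res.coefficient,
                        "p_value": res.p_value,
                        "n": res.n,
                        "k": res.k,
                    }
                )
        return pd.DataFrame(rows), dropped_total


@dataclass
class CohortStudyResults:
    """Fitted study: demographics table, partial-correlation grid, QC log."""

    model: CohortStudy
    table1: pd.DataFrame
    table2: pd.DataFrame
    n_enrolled: int
    n_analyzed: int
    exclusions: pd.DataFrame
    n_dropped_missing: int = 0

    def table2_grid(self, value: str = "coefficient") -> pd.DataFrame:
        """Pivot the partial-correlation rows into a parameter x outcome grid."""
        return self.table2.pivot(index="bp_parameter", columns="outcome", values=value)

    def summary(self) -> str:
        lines = [
            "Cohort study summary",
            "====================",
            f"enrolled: {self.n_enrolled}   analyzed: {self.n_analyzed}   "
            f"excluded: {len(self.exclusions)}",
            "",
            "Group comparisons",
            self.table1.to_string(
                index=False, float_format=lambda x: f"{x:.3f}"
            ),
            "",
            f"Partial correlations (controlling for {', '.join(self.model.covariates)})",
            self.table2_grid("coefficient").to_string(float_format=lambda x: f"{x:+.3f}"),
            "",
            "p-values",
            self.table2_grid("p_value").to_string(float_format=lambda x: f"{x:.3f}"),
        ]
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table1.to_csv(out / "table1.csv", index=False)
        self.table2.to_csv(out / "table2.csv", index=False)
        self.exclusions.to_csv(out / "exclusions.csv", index=False)
        (out / "report.json").write_text(
            json.dumps(
                {
                    "n_enrolled": self.n_enrolled,
                    "n_analyzed": self.n_analyzed,
                    "n_excluded": len(self.exclusions),
                    "n_dropped_missing": self.n_dropped_missing,
                    "t_variant": self.model.t_variant,
                    "covariates": list(self.model.covariates),
                },
                indent=2,
            )
        )


@dataclass(frozen=True)
class StudyConfig:
    """File-based configuration for an end-to-end run."""

    cohort_csv: str | Path
    bp_csv: str | Path | None = None
    image_dir: str | Path | None = None
    out_dir: str | Path = "study_out"
    t_variant: str = "pooled"
    quant_config: quant.QuantConfig = field(default_factory=quant.QuantConfig)


def quantify_image_dir(
    image_dir: str | Path, config: quant.QuantConfig = quant.QuantConfig()
) -> pd.DataFrame:
    """Quantify every PNG/TIFF angiogram in a directory.

    File stems are patient ids (an optional ``_OD``/``_OS`` suffix marks the
    eye; with two eyes the one with the higher pass-1 vessel fraction is
    selected, right eye on ties).  Images failing the quality guard are
    flagged, not dropped.
    """
    image_dir = Path(image_dir)
    rows = []
    for path in sorted(image_dir.glob("*")):
        if path.suffix.lower() not in (".png", ".tif", ".tiff"):
            continue
        stem = path.stem
        pid, _, eye = stem.partition("_")
        img = load_angiogram(path)
        try:
            res = quant.quantify_image(img, config)
            rows.append(
                {
                    "patient_id": pid,
                    "eye": eye or "OD",
                    "plexus": img.plexus.value,
                    "svp_density": res.parafoveal_vessel_density_pct,
                    "flow_void_area": res.parafoveal_flow_void_area_mm2,
                    "faz_area": res.faz_area_mm2,
                    "quality": res.vessel_fraction_pass1,
                    "qc_flag": "ok",
                }
            )
        except quant.RejectedImageError as err:
            rows.append(
                {
                    "patient_id": pid,
                    "eye": eye or "OD",
                    "plexus": img.plexus.value,
                    "svp_density": np.nan,
                    "flow_void_area": np.nan,
                    "faz_area": np.nan,
                    "quality": np.nan,
                    "qc_flag": f"rejected: {err}",
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    # per-patient eye selection
    chosen = []
    for pid, grp in df.groupby("patient_id", sort=True):
        ok = grp[grp["qc_flag"] == "ok"]
        pool = ok if len(ok) else grp
        quality = {r.eye: (r.quality if np.isfinite(r.quality) else -1.0) for r in pool.itertuples()}
        eye = select_eye(quality)
        chosen.append(pool[pool["eye"] == eye].iloc[0])
    return pd.DataFrame(chosen).reset_index(drop=True)


def run_study(cfg: StudyConfig) -> CohortStudyResults:
    """File-based end-to-end run: read tables (and optionally quantify
    images), fit the cohort study, and write the report to ``out_dir``."""
    cohort = pd.read_csv(cfg.cohort_csv)
    cohort["patient_id"] = cohort["patient_id"].astype(str)
    bp_visits = pd.read_csv(cfg.bp_csv) if cfg.bp_csv else None
    if cfg.image_dir is not None:
        metrics = quantify_image_dir(cfg.image_dir, cfg.quant_config)
        orphans = sorted(set(metrics["patient_id"]) - set(cohort["patient_id"]))
        if orphans:
            raise ReconciliationError(orphans)
        keep = ["patient_id", "svp_density", "flow_void_area", "faz_area", "qc_flag"]
        overlap = [c for c in keep[1:] if c in cohort.columns]
        cohort = cohort.drop(columns=overlap).merge(
            metrics[keep], on="patient_id", how="left"
        )
    study = CohortStudy.from_frames(cohort, bp_visits, t_variant=cfg.t_variant)
    results = study.fit()
    results.save(cfg.out_dir)
    return results
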