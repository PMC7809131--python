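"""Quality control and normalization of raw qPCR CT panels.

Plasma miRNA panels are screened for erythrocyte contamination (hemolysis),
non-detected assays are imputed, miRNAs are filtered by detection rate, and
expression is put on the global-mean ΔCT scale on which all downstream
analyses operate.  On that scale a difference of 1.0 CT cycle corresponds to
a twofold difference in expression, and *lower* ΔCT means *higher*
expression.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

#: absorbance at 414 nm above which free hemoglobin is suspicious
A414_THRESHOLD = 0.3
#: ΔCT(miR-23a-3p − miR-451a) above which erythrocyte miRNA is enriched
DELTA_CT_HEMOLYSIS_THRESHOLD = 7.0
#: default detection-rate threshold for calling a miRNA "expressed"
DETECTION_THRESHOLD = 0.80


@dataclass
class CtPanel:
    """Raw CT matrix (miRNA MIMAT id × sample id) with QC metadata.

    ``ct`` holds CT cycles with NaN for non-detects; ``detected`` mirrors it
    as a boolean mask.  ``panel_ok`` marks assays that are structurally
    valid: a plate half that failed amplification criteria makes its assays
    structurally missing for those samples (they are excluded from detection
    rates, not imputed).  Hemolysis metrics are per sample.
    """

    ct: pd.DataFrame
    detected: pd.DataFrame
    panel_ok: pd.DataFrame
    a414: pd.Series
    ct_mir23a: pd.Series
    ct_mir451a: pd.Series
    slc4a1_detected: pd.Series

    def __post_init__(self) -> None:
        if not self.ct.index.is_unique or not self.ct.columns.is_unique:
            raise ValueError("CT matrix ids must be unique")
        mismatch = self.ct.notna() ^ self.detected.astype(bool)
        if mismatch.to_numpy().any():
            raise ValueError("ct present ⇔ detected must hold entrywise")


@dataclass
class ExpressionMatrix:
    """Global-mean-normalized ΔCT values for the expressed miRNA set."""

    delta_ct: pd.DataFrame
    imputed: pd.DataFrame
    sample_mean_ct: pd.Series
    groups: pd.Series | None = None
    timepoints: pd.Series | None = None
    excluded_samples: dict[str, str] = field(default_factory=dict)


def assess_hemolysis(
    a414: float,
    ct_mir23a: float,
    ct_mir451a: float,
    slc4a1_detected: bool = False,
) -> dict:
    """Classify one plasma sample as pass/fail for hemolysis.

    A sample fails only when *both* indicators exceed their thresholds:
    absorbance at 414 nm strictly above 0.3 and ΔCT(miR-23a − miR-451a)
    strictly above 7 cycles.  Boundary values pass.  Detection of the
    erythrocyte transcript SLC4A1 is reported as a warning, not an
    exclusion.  Missing marker CTs leave the status indeterminate and the
    sample retained.
    """
    if ct_mir23a is None or ct_mir451a is None or np.isnan(ct_mir23a) or np.isnan(ct_mir451a):
        return {
            "status": "indeterminate",
            "warnings": ["hemolysis marker CT missing; sample retained"],
        }
    delta = ct_mir23a - ct_mir451a
    fail = (a414 > A414_THRESHOLD) and (delta > DELTA_CT_HEMOLYSIS_THRESHOLD)
    notes = []
    if slc4a1_detected:
        notes.append("erythrocyte transcript SLC4A1 detected")
    return {"status": "fail" if fail else "pass", "delta_ct": delta, "warnings": notes}


def hemolysis_table(panel: CtPanel) -> pd.DataFrame:
    """Per-sample hemolysis assessment for a whole panel."""
    rows = {}
    for s in panel.ct.columns:
        rows[s] = assess_hemolysis(
            panel.a414.get(s, np.nan),
            panel.ct_mir23a.get(s, np.nan),
            panel.ct_mir451a.get(s, np.nan),
            bool(panel.slc4a1_detected.get(s, False)),
        )
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def impute_nondetects(ct: pd.DataFrame, mirnas: list[str] | None = None) -> pd.DataFrame:
    """Replace non-detects by (max detected CT of that miRNA) + 1.

    Applied per miRNA across all samples pooled (the rule carries no group
    qualification).  A miRNA with zero detections cannot be imputed.
    """
    subset = list(ct.index) if mirnas is None else list(mirnas)
    out = ct.copy()
    block = out.loc[subset]
    n_detected = block.notna().sum(axis=1)
    if (n_detected == 0).any():
        bad = list(n_detected.index[n_detected == 0])
        raise ValueError(f"cannot impute miRNAs with zero detections: {bad}")
    fill = block.max(axis=1) + 1.0
    out.loc[subset] = block.apply(lambda row: row.fillna(fill[row.name]), axis=1)
    return out


def filter_expressed(
    detected: pd.DataFrame,
    groups: pd.Series,
    timepoints: pd.Series | None = None,
    threshold: float = DETECTION_THRESHOLD,
    panel_ok: pd.DataFrame | None = None,
) -> list[str]:
    """Keep miRNAs detected in ≥ ``threshold`` of samples in at least one
    group × timepoint cell.

    Samples whose plate half failed (``panel_ok`` False) are excluded from
    both numerator and denominator of the detection rate.
    """
    samples = detected.columns
    groups = groups.reindex(samples)
    if timepoints is None:
        timepoints = pd.Series("all", index=samples)
    else:
        timepoints = timepoints.reindex(samples)
    valid = (
        panel_ok.reindex(index=detected.index, columns=samples).fillna(True)
        if panel_ok is not None
        else pd.DataFrame(True, index=detected.index, columns=samples)
    )
    det = detected.astype(bool) & valid

    kept_mask = pd.Series(False, index=detected.index)
    for (_, _), cols in samples.to_series().groupby([groups, timepoints], observed=True):
        cell = cols.index
        denom = valid[cell].sum(axis=1)
        if (denom == 0).all():
            warnings.warn("empty group×timepoint cell skipped", stacklevel=2)
            continue
        rate = det[cell].sum(axis=1) / denom.replace(0, np.nan)
        kept_mask |= rate.ge(threshold).fillna(False)
    return list(detected.index[kept_mask])


def global_mean_normalize(
    ct: pd.DataFrame,
    imputed: pd.DataFrame | None = None,
    groups: pd.Series | None = None,
    timepoints: pd.Series | None = None,
) -> ExpressionMatrix:
    """ΔCT = CT − (per-sample mean CT over the expressed set).

    Must be run after imputation: no missing values are allowed, and the
    per-sample mean of the resulting ΔCT values is zero by construction.
    """
    if ct.isna().to_numpy().any():
        raise ValueError("CT matrix contains missing values; impute first")
    sample_mean = ct.mean(axis=0)
    delta = ct.sub(sample_mean, axis=1)
    if imputed is None:
        imputed = pd.DataFrame(False, index=ct.index, columns=ct.columns)
    return ExpressionMatrix(
        delta_ct=delta,
        imputed=imputed,
        sample_mean_ct=sample_mean,
        groups=groups,
        timepoints=timepoints,
    )


class GlobalMeanNormalizer(BaseEstimator, TransformerMixin):
    """Per-sample global-mean centering as an sklearn transformer.

    Rows are samples, columns are (expressed) miRNAs; ``transform``
    subtracts each row's mean so samples become comparable on the ΔCT
    scale.  Stateless: ``fit`` only records the feature count.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError("missing values; impute non-detects first")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X - X.mean(axis=1, keepdims=True)


def delta_delta_ct(expr: ExpressionMatrix | pd.DataFrame, groups: pd.Series) -> pd.Series:
    """ΔΔCT per miRNA: mean ΔCT(exposed) − mean ΔCT(control).

    Negative values indicate higher expression in the exposed group.
    """
    delta = expr.delta_ct if isinstance(expr, ExpressionMatrix) else expr
    groups = groups.reindex(delta.columns)
    present = set(groups.dropna().unique())
    if not {"control", "exposed"} <= present:
        raise ValueError(f"both groups required, found {sorted(present)}")
    exposed = delta.loc[:, (groups == "exposed").to_numpy()].mean(axis=1)
    control = delta.loc[:, (groups == "control").to_numpy()].mean(axis=1)
    return exposed - control


def run_qc(
    panel: CtPanel,
    groups: pd.Series,
    timepoints: pd.Series | None = None,
    threshold: float = DETECTION_THRESHOLD,
) -> tuple[ExpressionMatrix, dict]:
    """Full QC chain: hemolysis exclusion → expressed filter → imputation →
    global-mean normalization.  Returns the expression matrix and a QC
    report (JSON-serializable) listing excluded samples with reasons."""
    hemo = hemolysis_table(panel)
    excluded = {s: "hemolysis (A414 and ΔCT thresholds exceeded)"
                for s in hemo.index[hemo["status"] == "fail"]}
    keep_samples = [s for s in panel.ct.columns if s not in excluded]
    ct = panel.ct[keep_samples]
    detected = panel.detected[keep_samples]
    panel_ok = panel.panel_ok[keep_samples]
    g = groups.reindex(keep_samples)
    tp = timepoints.reindex(keep_samples) if timepoints is not None else None

    expressed = filter_expressed(detected, g, tp, threshold=threshold, panel_ok=panel_ok)
    ct_expr = ct.loc[expressed]
    imputed_mask = ct_expr.isna()
    ct_imp = impute_nondetects(ct_expr)
    expr = global_mean_normalize(ct_imp, imputed=imputed_mask, groups=g, timepoints=tp)
    expr.excluded_samples = excluded
    report = {
        "n_samples_in": int(panel.ct.shape[1]),
        "n_samples_kept": len(keep_samples),
        "excluded_samples": excluded,
        "n_mirnas_total": int(panel.ct.shape[0]),
        "n_expressed": len(expressed),
        "detection_threshold": threshold,
        "n_imputed_values": int(imputed_mask.to_numpy().sum()),
    }
    return expr, report


def write_qc_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
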