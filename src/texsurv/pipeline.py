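"""End-to-end study orchestration: simulate -> extract -> assemble -> model.

Produces, for each survival endpoint (OS, PFS):

* a univariate table with one Cox fit per biomarker in a fixed 19-variable
  order (six features at each timepoint, the size change, and the six change
  biomarkers);
* a combined table that starts from an IMDC-only baseline model and adds one
  candidate biomarker at a time, reporting per-covariate significance, -2LL
  and the 3.84 nested-model verdict;
* Kaplan-Meier median-split curves (CSV + PNG) for requested biomarkers.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .cohort import build_patient_table, extract_lesion_table
from .survival import (
    compare_nested,
    fit_cox,
    fit_cox_with_imdc,
    km_median_split,
)
from .synthetic import SimulationConfig, gen_cohort
from .texture import DEFAULT_HU_HIGH, DEFAULT_HU_LOW, DEFAULT_N_BINS, FilterSpec
from .types import IMDC_LEVELS

logger = logging.getLogger(__name__)

#: fixed row order of the univariate tables (column in the patient table, label)
UNIVARIATE_VARIABLES = [
    ("mpp_pre", "Mean positive pixel intensity prior to treatment"),
    ("mpp_post", "Mean positive pixel intensity following treatment"),
    ("sd_pre", "SD prior to treatment"),
    ("sd_post", "SD following treatment"),
    ("entropy_pre", "Entropy prior to treatment"),
    ("entropy_post", "Entropy following treatment"),
    ("nsd_pre", "nSD prior to treatment"),
    ("nsd_post", "nSD following treatment"),
    ("kurtosis_pre", "Kurtosis prior to treatment"),
    ("kurtosis_post", "Kurtosis following treatment"),
    ("skewness_pre", "Skewness prior to treatment"),
    ("skewness_post", "Skewness following treatment"),
    ("size_percent_change", "Percent change in size"),
    ("perc_mpp", "Mean positive pixel intensity change"),
    ("perc_sd", "SD change"),
    ("perc_entropy", "Entropy change"),
    ("perc_nsd", "nSD change"),
    ("perc_kurtosis", "Kurtosis change"),
    ("delta_skewness", "Skewness change"),
]

ENDPOINTS = {"os": ("os_days", "os_event"), "pfs": ("pfs_days", "pfs_event")}


def _endpoint_cols(endpoint: str) -> tuple[str, str]:
    try:
        return ENDPOINTS[endpoint.lower()]
    except KeyError:
        raise ValueError(f"endpoint must be one of {tuple(ENDPOINTS)}") from None


def run_univariate_table(patients: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    """One univariate Cox fit per biomarker, in the fixed 19-row order."""
    if patients.empty:
        raise ValueError("empty patient table")
    time_col, event_col = _endpoint_cols(endpoint)
    rows = []
    for column, label in UNIVARIATE_VARIABLES:
        row = {"variable": label, "column": column}
        try:
            fit = fit_cox(patients[[column]], patients[time_col], patients[event_col])
            row.update(
                p=fit.p_value(column), hr=float(fit.hr[0]),
                ci_low=float(fit.ci95_low[0]), ci_high=float(fit.ci95_high[0]),
                minus2ll=fit.minus2ll, n=fit.n, n_events=fit.n_events,
                converged=fit.converged,
            )
        except ValueError as exc:
            logger.warning("univariate %s (%s): %s", column, endpoint, exc)
            row.update(p=np.nan, hr=np.nan, ci_low=np.nan, ci_high=np.nan,
                       minus2ll=np.nan, n=0, n_events=0, converged=False)
        rows.append(row)
    return pd.DataFrame(rows)


def run_imdc_combined(
    patients: pd.DataFrame, endpoint: str, candidates: list[str], alpha: float = 0.05
) -> pd.DataFrame:
    """IMDC-only baseline plus one two-variable model per candidate biomarker.

    Each candidate row reports whether IMDC and the candidate stay
    significant in the combined model, the combined -2LL, and whether the
    drop from the baseline exceeds 3.84.  Candidate rows are fitted on their
    own complete cases; the baseline is refitted on the same risk set when
    missingness shrinks it.
    """
    time_col, event_col = _endpoint_cols(endpoint)
    labels = dict((c, l) for c, l in UNIVARIATE_VARIABLES)
    imdc_level = patients["imdc_group"].map(IMDC_LEVELS)

    base = fit_cox(pd.DataFrame({"imdc": imdc_level}), patients[time_col], patients[event_col])
    rows = [{
        "model": "IMDC alone",
        "imdc_p": base.p_value("imdc"),
        "imdc_significant": base.p_value("imdc") < alpha,
        "variable_p": np.nan, "variable_significant": np.nan,
        "minus2ll": base.minus2ll, "delta": np.nan,
        "significant_improvement": np.nan, "converged": base.converged,
    }]

    for column in candidates:
        label = labels.get(column, column)
        model_name = f"IMDC + {label}"
        complete = patients[[column, time_col, event_col]].notna().all(axis=1)
        sub = patients[complete]
        try:
            ext = fit_cox_with_imdc(
                sub[column], sub["imdc_group"], sub[time_col], sub[event_col], name=column
            )
            base_here = base
            if ext.n != base.n:
                base_here = fit_cox(
                    pd.DataFrame({"imdc": imdc_level[complete]}),
                    sub[time_col], sub[event_col],
                )
            if ext.converged and base_here.converged:
                cmp_ = compare_nested(base_here, ext)
                delta, improved = cmp_.delta, cmp_.significant_improvement
            else:
                delta, improved = np.nan, np.nan
            rows.append({
                "model": model_name,
                "imdc_p": ext.p_value("imdc"),
                "imdc_significant": ext.p_value("imdc") < alpha if ext.converged else np.nan,
                "variable_p": ext.p_value(column),
                "variable_significant": ext.p_value(column) < alpha if ext.converged else np.nan,
                "minus2ll": ext.minus2ll, "delta": delta,
                "significant_improvement": improved, "converged": ext.converged,
            })
        except ValueError as exc:
            logger.warning("combined model %s (%s): %s", column, endpoint, exc)
            rows.append({
                "model": model_name, "imdc_p": np.nan, "imdc_significant": np.nan,
                "variable_p": np.nan, "variable_significant": np.nan,
                "minus2ll": np.nan, "delta": np.nan,
                "significant_improvement": np.nan, "converged": False,
            })
    return pd.DataFrame(rows)


def km_table(curve) -> pd.DataFrame:
    return pd.DataFrame({
        "time_days": curve.times,
        "survival": curve.survival,
        "at_risk": curve.at_risk,
        "group": curve.label,
        "split_value": curve.split_value,
    })


def _km_plot(curves, path: Path, title: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for curve in curves:
        ax.step(curve.times, curve.survival, where="post", label=curve.label)
    ax.set_xlabel("days")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.set_title(title)
    ax.legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


# ---------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """Configuration of one full pipeline run.

    ``cohort_dir`` may point at an existing cohort (NIfTI + clinical.csv);
    when None, a synthetic cohort of ``n_patients`` is generated into the
    output directory first.
    """

    out_dir: str = "texsurv_out"
    cohort_dir: str | None = None
    n_patients: int = 60
    ssf_mm: float = FilterSpec.MEDIUM
    hu_low: float = DEFAULT_HU_LOW
    hu_high: float = DEFAULT_HU_HIGH
    n_bins: int = DEFAULT_N_BINS
    endpoints: tuple = ("os", "pfs")
    km_variables: tuple = ("nsd_pre", "nsd_post")
    imdc_candidates: tuple | None = None  # None -> univariate-significant variables
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        """Parse a flat ``key = value`` config file; unknown keys are errors."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            if key in ("endpoints", "km_variables", "imdc_candidates"):
                kwargs[key] = tuple(v.strip() for v in value.split(",") if v.strip())
            elif key in ("cohort_dir", "out_dir"):
                kwargs[key] = value
            elif key in ("n_patients", "n_bins", "seed"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


def run_all(config: StudyConfig) -> dict:
    """Execute the whole study; returns a manifest of written outputs.

    Deterministic under ``config.seed``: rerunning the same config writes
    byte-identical CSV tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"tables": [], "km": [], "cohort": None}

    # ---- stage 1: cohort -------------------------------------------------
    if config.cohort_dir is not None:
        cohort_dir = Path(config.cohort_dir)
        if not cohort_dir.is_dir():
            raise FileNotFoundError(f"cohort directory {cohort_dir} does not exist")
        logger.info("stage cohort: reading %s", cohort_dir)
        records = tio.read_cohort(cohort_dir)
    else:
        cohort_dir = out / "cohort"
        logger.info("stage cohort: simulating %d patients (seed %d)",
                    config.n_patients, config.seed)
        records, truth = gen_cohort(
            SimulationConfig(n_patients=config.n_patients, seed=config.seed)
        )
        tio.write_cohort(records, cohort_dir)
        tio.write_ground_truth(truth, cohort_dir)
    manifest["cohort"] = str(cohort_dir)

    # ---- stage 2: per-lesion features ------------------------------------
    spec = FilterSpec(ssf_mm=config.ssf_mm)
    logger.info("stage extract: ssf %.1f mm, HU window [%g, %g]",
                config.ssf_mm, config.hu_low, config.hu_high)
    lesion_features = extract_lesion_table(
        records, spec, config.hu_low, config.hu_high, config.n_bins
    )
    if lesion_features.empty:
        raise RuntimeError("stage extract: no usable lesions")
    features_csv = out / "lesion_features.csv"
    lesion_features.to_csv(features_csv, index=False)
    manifest["tables"].append(str(features_csv))

    # ---- stage 3: patient table ------------------------------------------
    patients = build_patient_table(records, lesion_features)
    if patients.empty:
        raise RuntimeError("stage assemble: no measurable patients")
    logger.info("stage assemble: %d/%d patients measurable", len(patients), len(records))
    patients_csv = out / "patients.csv"
    patients.to_csv(patients_csv, index=False)
    manifest["tables"].append(str(patients_csv))

    # ---- stage 4: survival models ----------------------------------------
    for endpoint in config.endpoints:
        uni = run_univariate_table(patients, endpoint)
        uni_csv = out / f"univariate_{endpoint}.csv"
        uni.to_csv(uni_csv, index=False)
        manifest["tables"].append(str(uni_csv))

        if config.imdc_candidates is None:
            significant = uni[(uni["p"] < 0.05) & uni["converged"]]["column"].tolist()
            candidates = significant or ["nsd_pre", "nsd_post"]
        else:
            candidates = list(config.imdc_candidates)
        combined = run_imdc_combined(patients, endpoint, candidates)
        combined_csv = out / f"imdc_combined_{endpoint}.csv"
        combined.to_csv(combined_csv, index=False)
        manifest["tables"].append(str(combined_csv))

        time_col, event_col = _endpoint_cols(endpoint)
        for var in config.km_variables:
            try:
                low, high = km_median_split(
                    patients[var], patients[time_col], patients[event_col], label=var
                )
            except ValueError as exc:
                logger.warning("KM %s (%s): %s", var, endpoint, exc)
                continue
            km_csv = out / f"km_{var}_{endpoint}.csv"
            pd.concat([km_table(low), km_table(high)]).to_csv(km_csv, index=False)
            png = out / f"km_{var}_{endpoint}.png"
            _km_plot(
                (low, high), png,
                f"{endpoint.upper()} by {var} (median {low.split_value:.3g})",
            )
            manifest["km"] += [str(km_csv), str(png)]

    # ---- metadata --------------------------------------------------------
    import lifelines
    import texsurv

    meta = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "n_patients_input": len(records),
        "n_patients_analyzed": len(patients),
        "versions": {
            "texsurv": texsurv.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "lifelines": lifelines.__version__,
        },
    }
    meta_path = out / "run_meta.json"
    meta_path.write_text(json.dumps(meta, indent=1, default=str))
    manifest["meta"] = str(meta_path)
    return manifest
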