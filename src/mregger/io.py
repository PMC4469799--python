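"""File I/O, run configuration and fixture generation.

The canonical on-disk format is a tab-delimited UTF-8 text file with header
columns ``variant_id, beta_exposure, se_exposure, beta_outcome, se_outcome``
and an optional ``eaf`` column (GWAS summary-statistics convention); CSV is
accepted on read, chosen by file extension.  Results are written as a JSON
record and a flat TSV, each embedding the seed, a hash of the run
configuration and the package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import MRDataset, orient
from .estimators import (
    cochran_q,
    ivw,
    mean_f_statistic,
    mr_egger,
    ratio_estimates,
)

__all__ = [
    "RunConfig",
    "SummaryDataError",
    "read_summary_data",
    "write_summary_data",
    "estimate_command",
    "generate_fixtures",
]

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = (
    "variant_id",
    "beta_exposure",
    "se_exposure",
    "beta_outcome",
    "se_outcome",
)
OPTIONAL_COLUMNS = ("eaf",)


class SummaryDataError(ValueError):
    """Malformed summary-statistics file."""


@dataclass(frozen=True)
class RunConfig:
    """Options for one `estimate` run."""

    input_path: str | Path
    output_path: str | Path
    se_model: str = "regression-output"
    ci_level: float = 0.95
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in asdict(self).items()}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _delimiter_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_summary_data(path: str | Path) -> MRDataset:
    """Read and validate a summary-statistics file into an :class:`MRDataset`.

    Column order is free but names are fixed.  Malformed rows are reported
    with their 1-based file line numbers (header is line 1).  Raises
    :class:`SummaryDataError` on a missing mandatory column, a non-numeric
    field, a non-positive standard error, an out-of-range allele frequency or
    duplicate variant ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_delimiter_for(path), dtype=str)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SummaryDataError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )
    has_eaf = "eaf" in df.columns
    numeric_cols = [c for c in MANDATORY_COLUMNS if c != "variant_id"]
    if has_eaf:
        numeric_cols.append("eaf")

    problems: list[str] = []
    values: dict[str, np.ndarray] = {}
    for col in numeric_cols:
        parsed = pd.to_numeric(df[col], errors="coerce")
        raw_missing = df[col].isna()
        for idx in df.index[parsed.isna() | raw_missing]:
            line = idx + 2  # header occupies line 1
            if raw_missing[idx]:
                problems.append(f"line {line}: missing value in column '{col}'")
            else:
                problems.append(
                    f"line {line}: non-numeric value {df[col][idx]!r} in column '{col}'"
                )
        values[col] = parsed.to_numpy(dtype=float)
    for col in ("se_exposure", "se_outcome"):
        bad = np.flatnonzero(values[col] <= 0)
        problems.extend(
            f"line {i + 2}: non-positive {col} ({values[col][i]})"
            for i in bad
            if np.isfinite(values[col][i])
        )
    if has_eaf:
        finite = np.isfinite(values["eaf"])
        bad = np.flatnonzero(finite & ((values["eaf"] <= 0) | (values["eaf"] >= 1)))
        problems.extend(
            f"line {i + 2}: eaf outside (0, 1) ({values['eaf'][i]})" for i in bad
        )
    ids = df["variant_id"].astype(str)
    dupes = ids[ids.duplicated()].unique()
    if len(dupes):
        problems.append(f"duplicate variant_id(s): {', '.join(dupes)}")
    if problems:
        raise SummaryDataError(f"{path}:\n  " + "\n  ".join(problems))

    return MRDataset.from_arrays(
        beta_exposure=values["beta_exposure"],
        se_exposure=values["se_exposure"],
        beta_outcome=values["beta_outcome"],
        se_outcome=values["se_outcome"],
        variant_ids=list(ids),
        eaf=values["eaf"] if has_eaf else None,
    )


def write_summary_data(dataset: MRDataset, path: str | Path) -> Path:
    """Write a dataset in the canonical delimited schema (TSV by default)."""
    path = Path(path)
    cols = {
        "variant_id": dataset.variant_ids,
        "beta_exposure": dataset.beta_exposure,
        "se_exposure": dataset.se_exposure,
        "beta_outcome": dataset.beta_outcome,
        "se_outcome": dataset.se_outcome,
    }
    if dataset.has_eaf:
        cols["eaf"] = dataset.eaf
    pd.DataFrame(cols).to_csv(
        path, sep=_delimiter_for(path), index=False, lineterminator="\n"
    )
    return path


# ---------------------------------------------------------------------------
# estimate subcommand
# ---------------------------------------------------------------------------


def _estimate_record(est) -> dict:
    rec = {
        "method": est.method,
        "slope": est.slope,
        "slope_se": est.slope_se,
        "slope_p": est.slope_p,
        "ci_lower": est.slope_ci_lower,
        "ci_upper": est.slope_ci_upper,
        "ci_level": est.ci_level,
        "df": est.df,
        "n_variants": est.n_variants,
        "se_model": est.se_model,
    }
    if est.method == "MR-Egger":
        rec.update(
            intercept=est.intercept,
            intercept_se=est.intercept_se,
            intercept_p=est.intercept_p,
        )
    return rec


def estimate_command(config: RunConfig) -> dict:
    """Read a summary file, run the full analysis and write the results.

    Orients the data, computes ratio estimates, IVW, MR-Egger, Cochran's Q
    and the mean F statistic; writes ``<output>.json`` (one record) and
    ``<output>.tsv`` (one row per method).  MR-Egger is skipped with a notice
    when fewer than 3 variants are available; IVW is still reported for J>=2.
    """
    dataset = read_summary_data(config.input_path)
    n_flips = int(np.sum(dataset.beta_exposure < 0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-gamma orientation warning -> log
        oriented = orient(dataset)
    logger.info(
        "read %d variants from %s; %d re-oriented", len(dataset), config.input_path, n_flips
    )

    results: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": __version__,
        "n_variants": len(dataset),
        "n_reoriented": n_flips,
        "mean_f_statistic": mean_f_statistic(oriented),
        "estimates": [],
        "notices": [],
    }
    results["estimates"].append(
        _estimate_record(ivw(oriented, se_model=config.se_model, ci_level=config.ci_level))
    )
    if len(oriented) >= 3:
        results["estimates"].append(
            _estimate_record(
                mr_egger(oriented, se_model=config.se_model, ci_level=config.ci_level)
            )
        )
    else:
        notice = "MR-Egger skipped: needs at least 3 variants"
        results["notices"].append(notice)
        logger.warning(notice)
    het = cochran_q(oriented)
    results["heterogeneity"] = {
        "q_statistic": het.q_statistic,
        "df": het.df,
        "p_value": het.p_value,
    }
    results["ratio_estimates"] = [
        {"variant_id": r.variant_id, "estimate": r.estimate, "se": r.se}
        for r in ratio_estimates(oriented)
    ]

    out = Path(config.output_path)
    json_path = out.with_suffix(".json")
    json_path.write_text(json.dumps(results, indent=2, sort_keys=True) + "\n")
    tsv_path = out.with_suffix(".tsv")
    pd.DataFrame(results["estimates"]).to_csv(
        tsv_path, sep="\t", index=False, lineterminator="\n"
    )
    logger.info("wrote %s and %s", json_path, tsv_path)
    return results


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def generate_fixtures(seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write synthetic example datasets emulating realistic file shapes.

    All files are generated from the given seed with documented parameters:

    ``continuous_180.tsv``
        180 variants under a valid-instrument model (slope 0.6, no
        pleiotropy, homogeneous) — the shape of a large continuous-outcome
        study.
    ``pleiotropic_29.tsv``
        29 variants with directional pleiotropy injected (mean direct effect
        0.02 on the outcome), so the MR-Egger intercept is nonzero by
        construction.
    ``affine_exact_4.tsv``
        4 variants with exactly affine structure, outcome = 0.1 + 2 * exposure,
        for hand-checking (MR-Egger recovers intercept 0.1, slope 2).
    ``affine_origin_3.tsv``
        3 variants with outcome exactly 0.5 * exposure through the origin.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    written: dict[str, Path] = {}

    def _noisy(n, slope, intercept_mean, sigma_scale, tag, noise_factor=1.0):
        # noise_factor < 1 makes the file under-dispersed relative to its
        # stated standard errors (a homogeneous dataset: Q below its df)
        gamma = rng.uniform(0.05, 0.25, n)
        se_x = np.full(n, 0.01)
        sigma = sigma_scale * rng.uniform(0.8, 1.2, n)
        big_gamma = (
            intercept_mean
            + slope * gamma
            + noise_factor * sigma * rng.standard_normal(n)
        )
        eaf = rng.uniform(0.1, 0.9, n)
        return MRDataset.from_arrays(
            beta_exposure=gamma,
            se_exposure=se_x,
            beta_outcome=big_gamma,
            se_outcome=sigma,
            variant_ids=[f"{tag}_{k + 1}" for k in range(n)],
            eaf=eaf,
        )

    written["continuous_180"] = write_summary_data(
        _noisy(
            180,
            slope=0.6,
            intercept_mean=0.0,
            sigma_scale=0.02,
            tag="cont",
            noise_factor=0.3,
        ),
        out_dir / "continuous_180.tsv",
    )
    written["pleiotropic_29"] = write_summary_data(
        _noisy(29, slope=0.05, intercept_mean=0.02, sigma_scale=0.004, tag="pleio"),
        out_dir / "pleiotropic_29.tsv",
    )

    gamma4 = np.array([0.1, 0.2, 0.3, 0.4])
    written["affine_exact_4"] = write_summary_data(
        MRDataset.from_arrays(
            beta_exposure=gamma4,
            se_exposure=np.full(4, 0.02),
            beta_outcome=0.1 + 2.0 * gamma4,
            se_outcome=np.full(4, 0.05),
            variant_ids=[f"aff_{k + 1}" for k in range(4)],
            eaf=np.full(4, 0.3),
        ),
        out_dir / "affine_exact_4.tsv",
    )
    gamma3 = np.array([0.1, 0.2, 0.3])
    written["affine_origin_3"] = write_summary_data(
        MRDataset.from_arrays(
            beta_exposure=gamma3,
            se_exposure=np.full(3, 0.02),
            beta_outcome=0.5 * gamma3,
            se_outcome=np.full(3, 0.05),
            variant_ids=[f"org_{k + 1}" for k in range(3)],
            eaf=np.full(3, 0.25),
        ),
        out_dir / "affine_origin_3.tsv",
    )

    params_path = out_dir / "GENERATING_PARAMETERS.json"
    params_path.write_text(
        json.dumps(
            {
                "seed": seed,
                "version": __version__,
                "continuous_180": {"slope": 0.6, "intercept": 0.0, "sigma": 0.02},
                "pleiotropic_29": {"slope": 0.05, "intercept": 0.02, "sigma": 0.004},
                "affine_exact_4": {"slope": 2.0, "intercept": 0.1},
                "affine_origin_3": {"slope": 0.5, "intercept": 0.0},
            },
            indent=2,
        )
        + "\n"
    )
    written["parameters"] = params_path
    return written
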