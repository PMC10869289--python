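"""End-to-end study runner: quantify every subject x muscle x model, compare
against the Dixon reference, and emit the agreement report.

The runner accepts either phantom cohorts (one cohort law per muscle label)
or a file manifest pointing at NIfTI volumes and masks.  For every muscle
series it computes, per model: Bland-Altman bias/SD/LOA, ICC(3,1) with its
reliability band, and the mean absolute error; then a 2x2 repeated-measures
ANOVA on the per-subject absolute errors (algorithm x components) and
post-hoc paired t-tests of the lowest-MAE model against the other three.

Left and right muscles are treated as separate series.  Every fit's seed is
derived deterministically from the study seed and the (subject, muscle,
model) coordinates, so identical configs produce byte-identical CSVs.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement
from .core import DixonPair, read_mask, read_volume, extract_roi_sample
from .phantom import CohortLaw, generate_cohort, reference_imf
from .thresholding import MODEL_IDS, imf_dixon, run_model

__all__ = ["StudyConfig", "StudyReport", "run_study", "load_study_config"]

log = logging.getLogger("imfquant.study")


@dataclass
class StudyConfig:
    """Validated study configuration.

    ``mode`` is "phantom" (cohort laws per muscle label) or "files" (a
    manifest of per-subject NIfTI paths).
    """

    mode: str = "phantom"
    models: tuple[str, ...] = MODEL_IDS
    seed: int = 0
    n_init: int = 50
    n_subjects: int = 30
    cohorts: dict[str, CohortLaw] = field(default_factory=dict)
    manifest: list[dict] = field(default_factory=list)
    out_dir: Path | None = None
    diagnostics: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("phantom", "files"):
            raise ValueError(f"mode must be 'phantom' or 'files', got {self.mode!r}")
        self.models = tuple(self.models)
        if not self.models:
            raise ValueError("model list must be non-empty")
        unknown = [m for m in self.models if m not in MODEL_IDS]
        if unknown:
            raise ValueError(f"unknown model ids {unknown}; expected subset of {MODEL_IDS}")
        if self.out_dir is not None:
            self.out_dir = Path(self.out_dir)


@dataclass
class StudyReport:
    """All study outputs as tidy tables plus structured test results."""

    imf_table: pd.DataFrame         # subject_id, muscle_label, model_id, imf_percent, counts, thresholds
    reference_table: pd.DataFrame   # subject_id, muscle_label, imf_percent
    agreement_table: pd.DataFrame   # muscle_label x model_id rows
    anova: dict                     # muscle_label -> rm-ANOVA + post-hoc t-tests
    failures: pd.DataFrame          # subject/muscle/model/stage/error

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.imf_table.to_csv(out_dir / "imf_results.csv", index=False)
        self.reference_table.to_csv(out_dir / "reference.csv", index=False)
        self.agreement_table.to_csv(out_dir / "agreement.csv", index=False)
        with open(out_dir / "anova.json", "w") as fh:
            json.dump(self.anova, fh, indent=2, sort_keys=True)
        if len(self.failures):
            self.failures.to_csv(out_dir / "failures.csv", index=False)
        return out_dir


def derive_seed(base_seed: int, *coords) -> int:
    """Stable per-fit seed from study seed and subject/muscle/model coords.

    CRC32-based so it is identical across platforms and Python processes;
    kept well below 2**31 to leave room for restart offsets.
    """
    tag = ":".join(str(c) for c in (base_seed, *coords)).encode()
    return int(zlib.crc32(tag) % (2**30))


def _collect_samples(config: StudyConfig):
    """Yield (subject_id, muscle_label, t2_sample, reference_imf_percent)."""
    if config.mode == "phantom":
        if not config.cohorts:
            raise ValueError("phantom mode requires at least one cohort law")
        for muscle_label, law in sorted(config.cohorts.items()):
            cohort_seed = derive_seed(config.seed, "cohort", muscle_label)
            subjects, _ = generate_cohort(config.n_subjects, law, seed=cohort_seed)
            for i, subj in enumerate(subjects):
                yield (f"S{i:03d}", muscle_label, subj.t2_sample, reference_imf(subj))
    else:
        for entry in config.manifest:
            subject_id = entry["subject_id"]
            t2 = read_volume(entry["t2"])
            pair = None
            if "dixon_fat" in entry:
                pair = DixonPair(
                    fat=read_volume(entry["dixon_fat"]),
                    water=read_volume(entry["dixon_water"]),
                )
            for muscle_label, mask_path in sorted(entry["masks"].items()):
                roi = read_mask(mask_path, muscle_label)
                sample = extract_roi_sample(t2, roi)
                ref = np.nan
                if pair is not None:
                    dixon_roi = read_mask(
                        entry.get("dixon_masks", entry["masks"])[muscle_label],
                        muscle_label,
                    )
                    ref = imf_dixon(pair, dixon_roi).imf_percent
                yield (subject_id, muscle_label, sample, ref)


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full comparison design and return the report tables.

    Any stage error is logged with its subject/muscle/model context and the
    run continues; failures are tabulated in the report.
    """
    imf_rows, ref_rows, failures = [], [], []
    for subject_id, muscle_label, sample, ref in _collect_samples(config):
        if np.isfinite(ref):
            ref_rows.append(
                {"subject_id": subject_id, "muscle_label": muscle_label,
                 "imf_percent": ref}
            )
        for model_id in config.models:
            fit_seed = derive_seed(config.seed, subject_id, muscle_label, model_id)
            try:
                fit, _, result = run_model(
                    sample, model_id, seed=fit_seed, n_init=config.n_init
                )
            except Exception as exc:  # run continues, failure tabulated
                log.warning("fit failed: %s/%s/%s: %s",
                            subject_id, muscle_label, model_id, exc)
                failures.append(
                    {"subject_id": subject_id, "muscle_label": muscle_label,
                     "model_id": model_id, "stage": "fit", "error": str(exc)}
                )
                continue
            thr = result.thresholds or ()
            imf_rows.append(
                {
                    "subject_id": subject_id,
                    "muscle_label": muscle_label,
                    "model_id": model_id,
                    "imf_percent": result.imf_percent,
                    "n_muscle": result.n_voxels_muscle,
                    "n_undefined": result.n_voxels_undefined,
                    "n_fat": result.n_voxels_fat,
                    "threshold_1": thr[0] if len(thr) > 0 else np.nan,
                    "threshold_2": thr[1] if len(thr) > 1 else np.nan,
                    "fit_seed": fit_seed,
                }
            )
    imf_table = pd.DataFrame(imf_rows)
    reference_table = pd.DataFrame(ref_rows)
    agreement_table, anova = evaluate_agreement(imf_table, reference_table)
    return StudyReport(
        imf_table=imf_table,
        reference_table=reference_table,
        agreement_table=agreement_table,
        anova=anova,
        failures=pd.DataFrame(failures),
    )


def evaluate_agreement(
    imf_table: pd.DataFrame, reference_table: pd.DataFrame, *, holm: bool = False
) -> tuple[pd.DataFrame, dict]:
    """Per-muscle, per-model agreement against the reference.

    Returns the agreement table (one row per muscle x model: bias, SD, LOA,
    ICC(3,1) with band, MAE) and a per-muscle dict with the 2x2 repeated-
    measures ANOVA on absolute errors plus post-hoc paired t-tests of the
    lowest-MAE model against the rest (unadjusted by default; ``holm``
    switches on the Holm step-down correction).
    """
    if not len(reference_table):
        return pd.DataFrame(), {}
    ref = reference_table.set_index(["subject_id", "muscle_label"])["imf_percent"]
    rows, anova_out = [], {}
    for muscle_label, group in imf_table.groupby("muscle_label", sort=True):
        wide = group.pivot(index="subject_id", columns="model_id",
                           values="imf_percent")
        try:
            ref_col = ref.xs(muscle_label, level="muscle_label").reindex(wide.index)
        except KeyError:
            continue
        keep = ref_col.notna()
        wide, ref_col = wide[keep], ref_col[keep]
        maes = {}
        for model_id in wide.columns:
            ok = wide[model_id].notna()
            if ok.sum() < 3:
                continue
            series = agreement.PairedSeries(
                subject_ids=tuple(wide.index[ok]),
                model_values=wide.loc[ok, model_id].to_numpy(),
                reference_values=ref_col[ok].to_numpy(),
            )
            rep = agreement.agreement_report(series)
            pearson_r = float(np.corrcoef(series.model_values,
                                          series.reference_values)[0, 1])
            maes[model_id] = rep.mae
            rows.append(
                {
                    "muscle_label": muscle_label,
                    "model_id": model_id,
                    "n": series.n,
                    "bias": rep.bias,
                    "sd_diff": rep.sd_diff,
                    "loa_lower": rep.loa_lower,
                    "loa_upper": rep.loa_upper,
                    "icc_3_1": rep.icc_3_1,
                    "icc_category": rep.icc_category,
                    "mae": rep.mae,
                    "pearson_r": pearson_r,
                }
            )
        if len(maes) == 4 and not wide.isna().any().any():
            abs_err = (wide[list(agreement.ANOVA_MODEL_ORDER)]
                       .sub(ref_col, axis=0).abs())
            res = agreement.rm_anova_2x2(abs_err)
            best = min(maes, key=maes.get)
            posthoc = {}
            others = [m for m in agreement.ANOVA_MODEL_ORDER if m != best]
            pvals = []
            for other in others:
                t, df, p = agreement.paired_t(abs_err[best], abs_err[other])
                posthoc[f"{best}_vs_{other}"] = {"t": t, "df": df, "p": p}
                pvals.append(p)
            if holm:
                for key, p_adj in zip(posthoc, agreement.holm_adjust(pvals)):
                    posthoc[key]["p_holm"] = float(p_adj)
            anova_out[muscle_label] = {
                "lowest_mae_model": best,
                "rm_anova": {
                    eff: {
                        "F": getattr(res, eff).F,
                        "df": list(getattr(res, eff).df),
                        "p": getattr(res, eff).p,
                        "degenerate": getattr(res, eff).degenerate,
                    }
                    for eff in ("algorithm", "components", "interaction")
                },
                "sphericity": res.sphericity,
                "posthoc_paired_t": posthoc,
            }
    return pd.DataFrame(rows), anova_out


def load_study_config(path: str | Path) -> StudyConfig:
    """Load and validate a YAML study configuration.

    Recognised keys: mode, models, seed, n_init, n_subjects, out_dir,
    diagnostics, cohorts (phantom mode: muscle label -> {law: multifidus|
    psoas, overrides...}), manifest (files mode: list of subject entries).
    """
    from .phantom import multifidus_like_law, psoas_like_law

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: study config must be a mapping")
    allowed = {"mode", "models", "seed", "n_init", "n_subjects", "cohorts",
               "manifest", "out_dir", "diagnostics"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    cohorts = {}
    for label, entry in (raw.pop("cohorts", None) or {}).items():
        entry = dict(entry or {})
        law_name = entry.pop("law", "multifidus")
        factory = {"multifidus": multifidus_like_law, "psoas": psoas_like_law}
        if law_name not in factory:
            raise ValueError(f"unknown cohort law {law_name!r}")
        entry.setdefault("muscle_label", label)
        cohorts[label] = factory[law_name](**entry)
    return StudyConfig(cohorts=cohorts, **raw)
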