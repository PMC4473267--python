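"""End-to-end orchestration: simulate -> template/masks -> normalize ->
evaluate -> classify.

The library functions here are what the CLI, the test suite and the
reproduction script all share: given a cohort they build the symmetric
control template and mask set, produce one normalized cohort per method
(``raw``, ``brall``, ``fgmm``, ``mse``), and compute the two study
readouts — the per-method KL homogeneity table and the per-method LOO
classification table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .binding_ratio import normalize_br_all
from .classification import loo_classify, report_tables, vaf_features
from .evaluation import cohort_kl
from .fgmm import fgmm_normalize
from .mse_norm import normalize_mse
from .phantom import PhantomConfig, generate_phantom
from .template import MaskSet, Template, build_masks, build_template, striatal_mask
from .volume_io import NC, Cohort, write_cohort, write_mask, write_volume

logger = logging.getLogger(__name__)

METHODS = ("raw", "brall", "fgmm", "mse")


@dataclass
class RunConfig:
    """Every knob of the pipeline, reachable from one YAML file.

    Defaults are the study values: k = 64 mixture components, 75%
    irrelevance rule, eta = 1/N (``eta = None`` means automatic), 0.45
    striatal ROI fraction.
    """

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    methods: tuple[str, ...] = METHODS
    k: int = 64
    eta: float | None = None
    irrelevance_fraction: float = 0.75
    striatal_fraction: float = 0.45
    brain_fraction: float = 0.10
    n_bins: int = 50
    pca_variance: float = 0.95
    svm_c: float = 1.0
    halve_template: bool = False
    ratio_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        phantom = PhantomConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in (raw.pop("phantom", {}) or {}).items()
        })
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(phantom=phantom, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["methods"] = list(self.methods)
        return d


def study_config(seed: int = 0) -> RunConfig:
    """The bundled 40-subject phantom study.

    A scale model of the canonical experiment: the 73 x 73 x 45 grid is
    rendered at 33 x 33 x 21 (same anatomy fractions; the point-spread
    blur shrinks proportionally because coarser voxels of the same brain
    mean a smaller PSF in voxel units), with k = 16 mixture components
    for the FGMM arm instead of 64.  Gain/offset corruption, noise and
    the PS uptake deficit keep their default values, so the cohort shows
    the inter-subject intensity variability the normalizers must remove.
    """
    shape = (33, 33, 21)
    phantom = PhantomConfig(
        shape=shape,
        n_nc=20,
        n_ps=20,
        psf_sigma=1.5 * shape[0] / 73,
        seed=seed,
    )
    return RunConfig(phantom=phantom, k=16, seed=seed)


def cohort_assets(
    cohort: Cohort,
    striatal_fraction: float = 0.45,
    brain_fraction: float = 0.10,
    halve_template: bool = False,
) -> tuple[Template, MaskSet]:
    """Template from the NC subset plus the derived mask set."""
    controls = cohort.subset(NC)
    template = build_template(controls, halve=halve_template)
    mean_nc = controls.mean_volume()
    masks = build_masks(
        template,
        mean_nc,
        striatal_fraction=striatal_fraction,
        brain_fraction=brain_fraction,
    )
    return template, masks


def normalize_cohort(
    cohort: Cohort,
    method: str,
    template: Template,
    masks: MaskSet,
    config: RunConfig,
) -> tuple[Cohort, pd.DataFrame | None]:
    """Apply one normalization method to every subject.

    Returns the normalized cohort and, for methods with per-subject fit
    parameters, a diagnostics table (MSE: a, b, xi_min).
    """
    if method == "raw":
        return cohort, None
    if method == "brall":
        volumes = [
            normalize_br_all(v, masks.nonspecific, ratio_only=config.ratio_only)
            for v in cohort.volumes
        ]
        return cohort.with_volumes(volumes), None
    if method == "mse":
        volumes, rows = [], []
        for sid, _, vol in cohort:
            normalized, fit = normalize_mse(vol, template.volume, masks.nonspecific)
            volumes.append(normalized)
            rows.append({"id": sid, "a": fit.a, "b": fit.b, "xi_min": fit.xi_min})
        return cohort.with_volumes(volumes), pd.DataFrame(rows)
    if method == "fgmm":
        volumes = []
        for i, (sid, _, vol) in enumerate(cohort):
            logger.debug("FGMM fit %s (%d/%d)", sid, i + 1, len(cohort))
            volumes.append(
                fgmm_normalize(
                    vol,
                    masks.striatal,
                    k=config.k,
                    seed=config.seed + i,
                    eta=config.eta,
                    irrelevance_fraction=config.irrelevance_fraction,
                )
            )
        return cohort.with_volumes(volumes), None
    raise ValueError(f"unknown method: {method}")


def normalize_all(
    cohort: Cohort, config: RunConfig
) -> tuple[dict[str, Cohort], dict[str, pd.DataFrame], Template, MaskSet]:
    """One normalized cohort per requested method, plus template and masks."""
    template, masks = cohort_assets(
        cohort,
        striatal_fraction=config.striatal_fraction,
        brain_fraction=config.brain_fraction,
        halve_template=config.halve_template,
    )
    cohorts: dict[str, Cohort] = {}
    diagnostics: dict[str, pd.DataFrame] = {}
    for method in config.methods:
        logger.info("normalizing cohort with method %s", method)
        cohorts[method], diag = normalize_cohort(cohort, method, template, masks, config)
        if diag is not None:
            diagnostics[method] = diag
    return cohorts, diagnostics, template, masks


def kl_tables(
    cohorts: dict[str, Cohort], masks: MaskSet, n_bins: int = 50
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Non-specific-region KL homogeneity, per subject and per method/class."""
    per_subject, summaries = [], []
    for method, cohort in cohorts.items():
        summary = cohort_kl(cohort, masks.nonspecific, n_bins=n_bins)
        sub = summary.per_subject()
        sub.insert(0, "method", method)
        per_subject.append(sub)
        summ = summary.summary()
        summ.insert(0, "method", method)
        summaries.append(summ)
    return pd.concat(per_subject, ignore_index=True), pd.concat(summaries, ignore_index=True)


def classification_tables(
    cohorts: dict[str, Cohort],
    config: RunConfig,
) -> pd.DataFrame:
    """LOO linear-SVM accuracy per method, for VAF and PCA feature sets.

    The ROI mask for each method is recomputed from that method's own
    mean-control image (0.45 max rule), so features always live in the
    intensity scale the method produces.
    """
    rows = []
    for method, cohort in cohorts.items():
        roi = striatal_mask(cohort.subset(NC).mean_volume(), config.striatal_fraction)
        features = vaf_features(cohort, roi)
        for feature_set, use_pca in (("vaf", False), ("pca", True)):
            rep = loo_classify(
                features,
                use_pca=use_pca,
                pca_variance=config.pca_variance,
                svm_c=config.svm_c,
            )
            table = report_tables({method: rep})
            table.insert(1, "features", feature_set)
            rows.append(table)
    return pd.concat(rows, ignore_index=True)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full study on a simulated cohort; returns the run dir.

    Writes NIfTI intermediates (template, masks, normalized volumes),
    the cohort/truth CSVs, Table-2-style KL CSVs, a Table-3/4-style
    classification CSV, and a machine-readable run manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        cohort, truth = generate_phantom(config.phantom)
        write_cohort(cohort, out_dir / "raw_volumes")
        truth.table.to_csv(out_dir / "truth.csv", index=False)

        stage = "build-template/make-masks"
        cohorts, diagnostics, template, masks = normalize_all(cohort, config)
        write_volume(template.volume, out_dir / "template.nii.gz")
        for name, mask in (
            ("striatal", masks.striatal),
            ("brain", masks.brain),
            ("nonspecific", masks.nonspecific),
        ):
            write_mask(mask, out_dir / f"mask_{name}.nii.gz")

        stage = "normalize"
        for method, normalized in cohorts.items():
            if method != "raw":
                write_cohort(normalized, out_dir / f"{method}_volumes")
        for method, diag in diagnostics.items():
            diag.to_csv(out_dir / f"{method}_fit.csv", index=False)

        stage = "evaluate"
        kl_subject, kl_summary = kl_tables(cohorts, masks, n_bins=config.n_bins)
        kl_subject.to_csv(out_dir / "kl_per_subject.csv", index=False)
        kl_summary.to_csv(out_dir / "kl_summary.csv", index=False)

        stage = "classify"
        classification = classification_tables(cohorts, config)
        classification.to_csv(out_dir / "classification.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "datnorm_version": __version__,
        "config": config.to_dict(),
        "outputs": sorted(p.name for p in out_dir.iterdir()),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir
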