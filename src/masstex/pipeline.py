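"""End-to-end experiment on synthetic patches: simulate -> preprocess ->
texton + deep features -> direct fusion and fusion-after-reduction -> CV.

This is the harness the CLI's ``pipeline`` subcommand and the acceptance
script drive.  It mirrors the comparison the method is built around: the
texton block alone, the deep block alone, their direct concatenation under a
softmax head, and the reduced-then-fused block under an RBF-SVM, all scored
with stratified 5-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

from .deep import DeepExtractorSpec, extract_deep
from .evaluate import ClassifierSpec, cross_validate
from .fusion import ReductionParams, cascade_fuse, fuse_after_reduction
from .mr8 import FilterBankConfig, build_mr8_bank
from .preprocess import equalize
from .synthetic import SynthConfig, generate_dataset
from .texton import LbpConfig, extract_texton_block

__all__ = ["ExperimentConfig", "run_experiment"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Desk-scale defaults: 80 patches of 96x96 keep a full run to ~1 minute."""

    n_per_class: int = 40
    patch_size: int = 96
    rotation_policy: str = "uniform_0_360"
    seed: int = 0
    apply_clahe: bool = True
    bank: FilterBankConfig = field(default_factory=FilterBankConfig)
    lbp: LbpConfig = field(default_factory=LbpConfig)
    deep: DeepExtractorSpec = field(default_factory=DeepExtractorSpec)
    reduction: ReductionParams = field(default_factory=lambda: ReductionParams(
        importance_trees=150, sfs_trees=50, max_candidates=25))
    svm_c: float = 1.0
    folds: int = 5


def run_experiment(cfg: ExperimentConfig | None = None) -> dict:
    """Run the full comparison; returns a flat dict of scores and dimensions."""
    cfg = cfg or ExperimentConfig()
    images, y = generate_dataset(SynthConfig(
        n_per_class=cfg.n_per_class, patch_size=cfg.patch_size,
        rotation_policy=cfg.rotation_policy, seed=cfg.seed))
    if cfg.apply_clahe:
        images = [equalize(img) for img in images]

    bank = build_mr8_bank(cfg.bank)
    texton_block = extract_texton_block(images, bank, cfg.lbp)
    deep_block = extract_deep(images, cfg.deep)

    cv_seed = (cfg.seed + 2) % (2 ** 31)
    softmax = ClassifierSpec(kind="softmax", seed=cfg.seed)
    svm = ClassifierSpec(kind="svm_rbf", hyperparams={"C": cfg.svm_c}, seed=cfg.seed)

    # direct-fusion arm (softmax head), plus single-block softmax baselines
    direct = cascade_fuse([texton_block, deep_block])
    texton_cv = cross_validate(texton_block, y, softmax, cfg.folds, cv_seed)
    deep_cv = cross_validate(deep_block, y, softmax, cfg.folds, cv_seed)
    direct_cv = cross_validate(direct, y, softmax, cfg.folds, cv_seed)

    # fusion-after-reduction arm (RBF-SVM), plus reduced single-block baselines
    red_params = ReductionParams(**{**asdict(cfg.reduction),
                                    "seed": (cfg.seed + 1) % (2 ** 31)})
    fused = fuse_after_reduction(texton_block, deep_block, y, red_params)
    sel_t = fused.selections["texton"].selected_indices
    sel_d = fused.selections["deep"].selected_indices
    texton_sel_cv = cross_validate(texton_block.subset(sel_t), y, svm, cfg.folds, cv_seed)
    deep_sel_cv = cross_validate(deep_block.subset(sel_d), y, svm, cfg.folds, cv_seed)
    fused_cv = cross_validate(fused.block, y, svm, cfg.folds, cv_seed)

    return {
        "n_images": len(images),
        "texton_dim": texton_block.length,
        "deep_dim": deep_block.length,
        "direct_fused_dim": direct.length,
        "n_selected_texton": len(sel_t),
        "n_selected_deep": len(sel_d),
        "n_selected_total": fused.block.length,
        "texton_softmax_acc": texton_cv.mean_acc,
        "texton_softmax_auc": texton_cv.mean_auc,
        "deep_softmax_acc": deep_cv.mean_acc,
        "deep_softmax_auc": deep_cv.mean_auc,
        "direct_fusion_acc": direct_cv.mean_acc,
        "direct_fusion_auc": direct_cv.mean_auc,
        "texton_selected_svm_acc": texton_sel_cv.mean_acc,
        "texton_selected_svm_auc": texton_sel_cv.mean_auc,
        "deep_selected_svm_acc": deep_sel_cv.mean_acc,
        "deep_selected_svm_auc": deep_sel_cv.mean_auc,
        "fused_reduced_svm_acc": fused_cv.mean_acc,
        "fused_reduced_svm_auc": fused_cv.mean_auc,
        "fused_reduced_svm_sens": fused_cv.mean_sens,
        "fused_reduced_svm_spec": fused_cv.mean_spec,
    }
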