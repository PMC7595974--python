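"""Development-stage assessment, design-strategy recommendation and
diagnostic figures.

Stage labels formalize the informal vocabulary of optimization practice
("early", "mid", "late") as a pure function of the saturation score S
and the progression score P: high saturation marks well-explored
series-centric space; high progression marks SAR that still responds
strongly to small modifications.  The thresholds are configuration, not
doctrine, and every assessment records the thresholds used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .nbh import ScoreReport

logger = logging.getLogger(__name__)

STAGE_ORDER = ("early", "early_mid", "mid", "late")

DEFAULT_THRESHOLDS = {"s_late": 0.5, "p_active": 0.8}

#: design strategies ranked per stage: conservative routes for saturated
#: series, explorative routes for early ones
DEFAULT_STRATEGY_MAP = {
    "late": ("fw", "close_in", "sampled", "diverse"),
    "mid": ("close_in", "fw", "sampled", "diverse"),
    "early_mid": ("diverse", "sampled", "close_in", "fw"),
    "early": ("diverse", "sampled", "close_in", "fw"),
}


@dataclass(frozen=True)
class StageAssessment:
    s_score: float
    p_score: float
    stage_label: str
    rationale: str
    thresholds: dict = field(default_factory=dict)


def classify_stage(
    report: ScoreReport, thresholds: Optional[dict] = None
) -> StageAssessment:
    """Deterministic 2x2 stage call from (S, P).

    S above the saturation threshold puts the series in the later half
    (late if P is below the progression threshold, else mid); S below
    it puts the series in the earlier half (early_mid if P is active,
    else early).  Increasing S at fixed P never yields an earlier
    label.
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    s, p = report.s_mean, report.p_mean
    saturated = s >= thr["s_late"]
    progressing = p >= thr["p_active"]
    if saturated:
        label = "mid" if progressing else "late"
    else:
        label = "early_mid" if progressing else "early"
    if s == 0.0:
        label = "early"
    rationale = (
        f"S={s:.2f} ({'>=' if saturated else '<'} {thr['s_late']}), "
        f"P={p:.2f} ({'>=' if progressing else '<'} {thr['p_active']}): "
        f"{'saturated' if saturated else 'unsaturated'} chemical space with "
        f"{'active' if progressing else 'flat'} SAR progression"
    )
    return StageAssessment(
        s_score=s,
        p_score=p,
        stage_label=label,
        rationale=rationale,
        thresholds=thr,
    )


def recommend_strategy(
    assessment: StageAssessment,
    strategy_map: Optional[dict] = None,
) -> tuple[str, ...]:
    """Ranked design strategies for the assessed stage."""
    mapping = dict(DEFAULT_STRATEGY_MAP)
    if strategy_map:
        mapping.update(strategy_map)
    return tuple(mapping[assessment.stage_label])


def render_figures(
    out_dir: str,
    populations: Optional[dict] = None,
    epoch_metrics: Optional[Sequence] = None,
    score_report: Optional[ScoreReport] = None,
    prediction_summary: Optional[dict] = None,
    descriptor_set=None,
    fmt: str = "png",
) -> list[str]:
    """Render whichever diagnostic figures the inputs support.

    populations: name -> list of CompoundRecord (PCA scatter of the
    joint descriptor space, axes annotated with explained variance);
    epoch_metrics: EpochMetrics sequence (per-epoch sampling curves);
    score_report: score bars with sd; prediction_summary: per-origin
    boxplot quantiles.  Missing inputs skip their figure with a log
    entry.  Returns the written file paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .chemspace import descriptor_matrix, project_pca
    from .records import DEFAULT_DESCRIPTORS

    import os

    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []

    if populations:
        names = list(populations)
        mats = {
            n: descriptor_matrix(populations[n], descriptor_set or DEFAULT_DESCRIPTORS)
            for n in names
        }
        joint = np.vstack([mats[n] for n in names])
        coords, evr = project_pca(joint, k=2)
        fig, ax = plt.subplots(figsize=(6, 5))
        offset = 0
        for n in names:
            m = len(mats[n])
            ax.scatter(
                coords[offset : offset + m, 0],
                coords[offset : offset + m, 1],
                s=12,
                alpha=0.6,
                label=n,
            )
            offset += m
        ax.set_xlabel(f"PC1 ({evr[0] * 100:.1f}% of variance)")
        if len(evr) > 1:
            ax.set_ylabel(f"PC2 ({evr[1] * 100:.1f}% of variance)")
        ax.legend()
        path = os.path.join(out_dir, f"pca_populations.{fmt}")
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    else:
        logger.info("no populations given; skipping PCA figure")

    if epoch_metrics:
        fig, ax = plt.subplots(figsize=(6, 4))
        epochs = [m.epoch for m in epoch_metrics]
        for attr, label in (
            ("n_valid", "valid"),
            ("n_unique", "unique"),
            ("n_with_core", "with core"),
            ("n_reproduced_eas", "reproduced analogs"),
        ):
            ax.plot(epochs, [getattr(m, attr) for m in epoch_metrics], marker="o", label=label)
        ax.set_xlabel("epoch")
        ax.set_ylabel("sampled compounds")
        ax.legend()
        path = os.path.join(out_dir, f"epoch_curves.{fmt}")
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    else:
        logger.info("no epoch metrics given; skipping sampling curves")

    if score_report:
        fig, ax = plt.subplots(figsize=(5, 4))
        names = ["C", "D", "S", "P"]
        means = [
            score_report.c_mean,
            score_report.d_mean,
            score_report.s_mean,
            score_report.p_mean,
        ]
        sds = [
            score_report.c_sd,
            score_report.d_sd,
            score_report.s_sd,
            score_report.p_sd,
        ]
        ax.bar(names, means, yerr=sds, capsize=4)
        ax.set_ylabel("score")
        ax.set_title(f"radius={score_report.radius:g}, n={score_report.sample_size}")
        path = os.path.join(out_dir, f"scores.{fmt}")
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    else:
        logger.info("no score report given; skipping score bars")

    if prediction_summary:
        fig, ax = plt.subplots(figsize=(6, 4))
        names = list(prediction_summary)
        stats = [
            {
                "med": prediction_summary[n]["median"],
                "q1": prediction_summary[n]["q1"],
                "q3": prediction_summary[n]["q3"],
                "whislo": prediction_summary[n]["min"],
                "whishi": prediction_summary[n]["max"],
                "label": n,
            }
            for n in names
        ]
        ax.bxp(stats, showfliers=False)
        ax.set_ylabel("predicted pIC50")
        path = os.path.join(out_dir, f"prediction_boxplots.{fmt}")
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    else:
        logger.info("no prediction summary given; skipping boxplots")

    return written
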