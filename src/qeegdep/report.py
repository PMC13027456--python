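"""Optional figures: score distribution and TBR-versus-score scatter."""

from __future__ import annotations

from typing import Sequence

from .pipeline import SubjectResult


def plot_score_distribution(results: Sequence[SubjectResult], path,
                            config=None) -> None:
    """Histogram of dependence scores with the decision thresholds marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .scoring import ScoringConfig

    c = config or ScoringConfig()
    scores = [r.score.dependence_score for r in results]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(scores, bins=20, range=(0, 1), color="#4878a8",
            edgecolor="white")
    for x, name in ((c.borderline_score, "borderline"),
                    (c.dependent_score, "dependence-related")):
        ax.axvline(x, linestyle="--", color="0.3")
        ax.text(x, ax.get_ylim()[1] * 0.95, f" {name} ≥ {x}",
                rotation=90, va="top", fontsize=8)
    ax.set_xlabel("Dependence score")
    ax.set_ylabel("Subjects")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tbr_vs_score(results: Sequence[SubjectResult], path) -> None:
    """Scatter of background TBR against dependence score."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tbr = [r.indices.tbr_background for r in results]
    score = [r.score.dependence_score for r in results]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(tbr, score, s=18, alpha=0.8, color="#4878a8")
    ax.set_xlabel("Theta/beta ratio (background)")
    ax.set_ylabel("Dependence score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
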