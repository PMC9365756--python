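"""Graphical evaluation outputs.

Every plot writes its data series alongside the image as CSV, so figures
are auditable without rendering. Matplotlib's Agg backend is forced: the
tool is meant for headless batch runs.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .classifiers import MetricsReport
from .evo_core import ContractError, ConvergenceTrace, ParetoFront


def _save(fig, out: Path) -> None:
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_pareto(front: ParetoFront, out: str | Path) -> Path:
    out = Path(out)
    pts = np.asarray(front.objectives())
    df = pd.DataFrame(pts, columns=["objective1", "objective2"])
    df.to_csv(out.with_suffix(".csv"), index=False)
    fig, ax = plt.subplots(figsize=(5, 4))
    order = np.argsort(pts[:, 0])
    ax.plot(pts[order, 0], pts[order, 1], "o-")
    ax.set_xlabel("fitness 1 (performance)")
    ax.set_ylabel("fitness 2 (1 - length / num features)")
    ax.set_xlim(0, 1.02)
    ax.set_ylim(0, 1.02)
    ax.set_title("Pareto front")
    _save(fig, out)
    return out


def plot_convergence(traces: list[ConvergenceTrace], out: str | Path) -> Path:
    out = Path(out)
    rows = []
    for t in traces:
        for g in t.generations:
            rows.append({"restart": t.restart, "generation": g["generation"],
                         "best_obj1": g["best"][0], "mean_obj1": g["mean"][0]})
    pd.DataFrame(rows).to_csv(out.with_suffix(".csv"), index=False)
    fig, ax = plt.subplots(figsize=(6, 4))
    for t in traces:
        gens = [g["generation"] for g in t.generations]
        ax.plot(gens, t.best_series(0), label=f"best (restart {t.restart})")
        ax.plot(gens, [g["mean"][0] for g in t.generations], "--",
                label=f"mean (restart {t.restart})", alpha=0.6)
    ax.set_xlabel("generation")
    ax.set_ylabel("fitness 1")
    ax.legend(fontsize=7)
    ax.set_title("Convergence")
    _save(fig, out)
    return out


def plot_confusion(report: MetricsReport, out: str | Path) -> Path:
    out = Path(out)
    cm = np.asarray(report.confusion)
    pd.DataFrame(cm, index=report.classes, columns=report.classes).to_csv(out.with_suffix(".csv"))
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.imshow(cm, cmap="Blues")
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            ax.text(j, i, str(cm[i, j]), ha="center", va="center")
    ax.set_xticks(range(len(report.classes)), report.classes)
    ax.set_yticks(range(len(report.classes)), report.classes)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(f"Confusion matrix (acc={report.accuracy:.3f})")
    _save(fig, out)
    return out


def plot_roc(report: MetricsReport, out: str | Path) -> Path:
    out = Path(out)
    if not report.roc:
        raise ContractError("report carries no ROC curves (no scores were given)")
    rows = []
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, curve in report.roc.items():
        ax.plot(curve["fpr"], curve["tpr"], label=f"{cls} (AUC={curve['auc']:.3f})")
        rows += [{"class": cls, "fpr": f, "tpr": t} for f, t in zip(curve["fpr"], curve["tpr"])]
    pd.DataFrame(rows).to_csv(out.with_suffix(".csv"), index=False)
    ax.plot([0, 1], [0, 1], "k--", alpha=0.4)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=8)
    ax.set_title("One-vs-rest ROC")
    _save(fig, out)
    return out


def plot_comparison(metrics_by_model: dict[str, MetricsReport], reference: str,
                    out: str | Path) -> Path:
    """Per-model metric deltas against a named reference model."""
    out = Path(out)
    if reference not in metrics_by_model:
        raise ContractError(f"reference model {reference!r} not among the results")
    names = ["accuracy", "precision", "recall", "specificity", "f1"]
    ref = metrics_by_model[reference]
    rows = []
    for model, rep in metrics_by_model.items():
        for m in names:
            rows.append({"model": model, "metric": m,
                         "value": getattr(rep, m), "delta": getattr(rep, m) - getattr(ref, m)})
    df = pd.DataFrame(rows)
    df.to_csv(out.with_suffix(".csv"), index=False)
    fig, ax = plt.subplots(figsize=(7, 4))
    models = [m for m in metrics_by_model if m != reference]
    width = 0.8 / max(len(models), 1)
    xs = np.arange(len(names))
    for i, model in enumerate(models):
        deltas = [df[(df.model == model) & (df.metric == m)].delta.iloc[0] for m in names]
        ax.bar(xs + i * width, deltas, width, label=model)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xticks(xs + 0.4 - width / 2, names)
    ax.set_ylabel(f"delta vs {reference}")
    ax.legend(fontsize=8)
    ax.set_title("Model comparison")
    _save(fig, out)
    return out


def export_decision_tree(model, feature_names: list[str], class_names: list[str],
                         out: str | Path) -> Path:
    """DOT export of a fitted sklearn decision tree: split rules on internal
    nodes, class shares at the leaves."""
    from sklearn.tree import export_graphviz

    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    export_graphviz(
        model, out_file=str(out), feature_names=feature_names,
        class_names=class_names, filled=False, proportion=True,
    )
    return out


def plot_ge_tree(tree, out: str | Path) -> Path:
    """DOT export of a derivation tree."""
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    lines = ["digraph derivation {"]
    counter = [0]

    def walk(node) -> int:
        my = counter[0]
        counter[0] += 1
        kind, val = node.symbol
        label = f"<{val}>" if kind == "NT" else val.replace('"', r"\"")
        lines.append(f'  n{my} [label="{label}"];')
        for c in node.children:
            cid = walk(c)
            lines.append(f"  n{my} -> n{cid};")
        return my

    walk(tree.root)
    lines.append("}")
    out.write_text("\n".join(lines))
    return out
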