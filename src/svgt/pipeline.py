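"""End-to-end orchestration: genotype calling, evaluation, and the
copy-number x coverage accuracy grid.

The evaluation follows the protocol used throughout the method's assessment:
accuracy is the fraction of test calls whose predicted class matches the
planted truth; predictions whose five class probabilities tie (typically a
test point far from every relevance vector, leaving all classes at 1/5) are
*invalid samples* -- they count as errors in the overall accuracy, and the
valid-sample accuracy is recomputed over the remaining calls.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .io import CLASS_ORDER, SVCall, build_vcf_header
from .features import extract_feature_matrix
from .mrvm import MRVMClassifier
from .simulate import SimConfig, simulate_dataset

#: One-hot label vectors: N = [0,0,0,0,1], G1 = [0,0,0,1,0], ... G4 = [1,0,0,0,0].
#: Probability vectors are always laid out in CLASS_ORDER (N, G1, G2, G3, G4).
ONE_HOT = {
    cls: tuple(1 if i == len(CLASS_ORDER) - 1 - k else 0 for i in range(len(CLASS_ORDER)))
    for k, cls in enumerate(CLASS_ORDER)
}

TIE_TOLERANCE = 1e-9


@dataclass(frozen=True)
class GenotypeCall:
    """A genotyped candidate: class probabilities and the argmax label."""

    call_id: str
    probabilities: tuple[float, ...]  # in CLASS_ORDER
    label: str
    is_tie: bool

    @property
    def one_hot(self) -> tuple[int, ...]:
        return ONE_HOT[self.label]


def predict_label(call_id: str, probabilities: Sequence[float]) -> GenotypeCall:
    """Argmax genotype with tie detection.

    A tie is flagged when more than one class attains the maximum probability
    within ``TIE_TOLERANCE``; the reported label is then the first class in
    the fixed order N < G1 < G2 < G3 < G4 (deterministic), and downstream
    evaluation treats the call as invalid.
    """
    p = np.asarray(probabilities, dtype=float)
    if p.shape != (len(CLASS_ORDER),):
        raise ValueError(f"expected {len(CLASS_ORDER)} probabilities, got {p.shape}")
    if np.any(p < -TIE_TOLERANCE) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"call {call_id}: probabilities not normalized: {p}")
    top = p.max()
    winners = np.flatnonzero(p >= top - TIE_TOLERANCE)
    return GenotypeCall(
        call_id=call_id,
        probabilities=tuple(float(x) for x in p),
        label=CLASS_ORDER[int(winners[0])],
        is_tie=winners.shape[0] > 1,
    )


def genotype_calls(
    model: MRVMClassifier, features: pd.DataFrame
) -> list[GenotypeCall]:
    """Predict per-call class probabilities and labels from a feature table."""
    if len(features) == 0:
        return []
    proba = model.predict_proba(features.to_numpy(dtype=float))
    # reindex the model's class columns into the fixed genotype order
    cols = {str(c): i for i, c in enumerate(model.classes_)}
    out = []
    for call_id, row in zip(features.index, proba):
        p = np.zeros(len(CLASS_ORDER))
        for k, cls in enumerate(CLASS_ORDER):
            if cls in cols:
                p[k] = row[cols[cls]]
        out.append(predict_label(str(call_id), p))
    return out


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    overall_accuracy: float
    n_samples: int
    n_invalid: int
    valid_accuracy: float
    confusion: pd.DataFrame  # truth rows x predicted columns
    n_correct: int

    def summary(self) -> str:
        return (
            f"accuracy {self.overall_accuracy:.4f} on {self.n_samples} samples "
            f"({self.n_invalid} invalid); valid-sample accuracy "
            f"{self.valid_accuracy:.4f}"
        )


def valid_sample_accuracy(
    overall_accuracy: float, n_samples: int, n_invalid: int
) -> float:
    """Valid-sample accuracy from a printed overall accuracy.

    The correct count is recovered by nearest-integer rounding of
    ``overall_accuracy * n_samples`` and re-divided by the valid sample count
    ``n_samples - n_invalid`` (ties are counted as errors overall, so the
    correct calls are all among the valid ones).
    """
    if n_invalid > n_samples:
        raise ValueError("n_invalid exceeds n_samples")
    n_correct = int(round(overall_accuracy * n_samples))
    return n_correct / (n_samples - n_invalid)


def evaluate_accuracy(
    calls: Sequence[GenotypeCall], truth: Mapping[str, str]
) -> EvaluationReport:
    """Score predictions against truth labels aligned by call id."""
    missing = [c.call_id for c in calls if c.call_id not in truth]
    if missing:
        raise ValueError(f"calls without truth labels: {missing[:5]}")
    n = len(calls)
    n_invalid = sum(1 for c in calls if c.is_tie)
    n_correct = sum(
        1 for c in calls if not c.is_tie and c.label == truth[c.call_id]
    )
    confusion = pd.DataFrame(
        0, index=list(CLASS_ORDER), columns=list(CLASS_ORDER), dtype=int
    )
    for c in calls:
        confusion.loc[truth[c.call_id], c.label] += 1
    overall = n_correct / n if n else 0.0
    valid = n_correct / (n - n_invalid) if n > n_invalid else 0.0
    return EvaluationReport(
        overall_accuracy=overall,
        n_samples=n,
        n_invalid=n_invalid,
        valid_accuracy=valid,
        confusion=confusion,
        n_correct=n_correct,
    )


# ---------------------------------------------------------------------------
# Grid experiment
# ---------------------------------------------------------------------------


@dataclass
class GridSpec:
    """The copy-number x coverage evaluation grid.

    Each cell simulates ``repeats`` independent train/test dataset pairs
    (identical configuration, distinct seeds), trains the classifier on the
    train set and scores the test set; cell results average the repeats.
    """

    copy_numbers: tuple[int, ...] = (2, 3, 4, 5)
    coverages: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0)
    repeats: int = 5
    base_config: SimConfig = field(default_factory=SimConfig)
    kernel_param: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def _cell_seed(base_seed: int, copy_number: int, coverage: float, repeat: int,
               role: int) -> int:
    """Deterministic per-(cell, repeat, role) seed below 2**31."""
    ss = np.random.SeedSequence(
        entropy=int(base_seed),
        spawn_key=(int(copy_number), int(round(coverage * 10)), int(repeat), role),
    )
    return int(ss.generate_state(1)[0] % (2**31))


def run_cell(
    cfg: SimConfig, kernel_param: float, train_seed: int, test_seed: int
) -> dict:
    """One train/test repeat of a grid cell; returns accuracy and model stats."""
    stats = cfg.insert_stats()
    results = {}
    feats = {}
    labels = {}
    for role, seed in (("train", train_seed), ("test", test_seed)):
        sim = simulate_dataset(dataclasses.replace(cfg, seed=seed))
        mat = extract_feature_matrix(
            sim.calls,
            sim.collection,
            stats,
            read_length=cfg.read_length,
            reference_length=cfg.region_length,
        )
        feats[role] = mat
        labels[role] = sim.labels
    model = MRVMClassifier(kernel_param=kernel_param).fit(
        feats["train"].to_numpy(dtype=float),
        np.asarray([labels["train"][i] for i in feats["train"].index]),
    )
    calls = genotype_calls(model, feats["test"])
    report = evaluate_accuracy(calls, labels["test"])
    results.update(
        accuracy=report.overall_accuracy,
        valid_accuracy=report.valid_accuracy,
        n_invalid=report.n_invalid,
        n_samples=report.n_samples,
        n_relevance_vectors=model.n_relevance_vectors_,
        initial_relevance_vectors=int(model.trace_["n_relevance_vectors"].iloc[0]),
        n_iter=model.n_iter_,
        converged=model.converged_,
    )
    return results


def run_grid_experiment(grid: GridSpec, progress: bool = False) -> pd.DataFrame:
    """Per-repeat log of the full grid (one row per cell repeat).

    Aggregate with :func:`summarize_grid`.
    """
    rows = []
    for cn in grid.copy_numbers:
        for cov in grid.coverages:
            cfg = dataclasses.replace(
                grid.base_config, copy_number=cn, coverage=float(cov)
            )
            for rep in range(grid.repeats):
                train_seed = _cell_seed(grid.seed, cn, cov, rep, 0)
                test_seed = _cell_seed(grid.seed, cn, cov, rep, 1)
                try:
                    res = run_cell(cfg, grid.kernel_param, train_seed, test_seed)
                except Exception as exc:
                    raise RuntimeError(
                        f"grid cell copy_number={cn} coverage={cov} repeat={rep}: {exc}"
                    ) from exc
                rows.append(
                    {
                        "copy_number": cn,
                        "coverage": cov,
                        "repeat": rep,
                        "train_seed": train_seed,
                        "test_seed": test_seed,
                        **res,
                    }
                )
                if progress:
                    print(
                        f"cell cn={cn} cov={cov} rep={rep}: "
                        f"accuracy={res['accuracy']:.4f}",
                        flush=True,
                    )
    return pd.DataFrame(rows)


def summarize_grid(log: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean/sd accuracy and mean relevance-vector count."""
    g = log.groupby(["copy_number", "coverage"])
    out = g.agg(
        mean_accuracy=("accuracy", "mean"),
        sd_accuracy=("accuracy", "std"),
        mean_relevance_vectors=("n_relevance_vectors", "mean"),
        repeats=("accuracy", "size"),
    ).reset_index()
    return out


# ---------------------------------------------------------------------------
# Genotyping command and trace report
# ---------------------------------------------------------------------------


def genotype_to_tables(
    calls: Sequence[GenotypeCall],
) -> pd.DataFrame:
    rows = [
        {
            "call_id": c.call_id,
            **{f"p_{cls}": c.probabilities[i] for i, cls in enumerate(CLASS_ORDER)},
            "label": c.label,
            "is_tie": c.is_tie,
        }
        for c in calls
    ]
    cols = (
        ["call_id"] + [f"p_{cls}" for cls in CLASS_ORDER] + ["label", "is_tie"]
    )
    return pd.DataFrame(rows, columns=cols)


def annotate_vcf(
    calls: Sequence[SVCall],
    genotyped: Sequence[GenotypeCall],
    out_path: str | Path,
    chrom: str,
    reference_length: int,
) -> None:
    """Write a VCF carrying GTCLASS and the five class probabilities."""
    by_id = {g.call_id: g for g in genotyped}
    extra = [("GTCLASS", "1", "String", "Predicted genotype class")] + [
        (f"P{cls}", "1", "Float", f"Probability of class {cls}")
        for cls in CLASS_ORDER
    ]
    header = build_vcf_header(chrom, reference_length, extra_info=extra)
    with pysam.VariantFile(str(out_path), "w", header=header) as vf:
        for c in sorted(calls, key=lambda c: c.pos):
            rec = vf.new_record(
                contig=chrom,
                start=c.pos - 1,
                stop=c.end,
                alleles=("N", f"<{c.sv_type}>"),
                id=c.id,
            )
            rec.info["SVTYPE"] = c.sv_type
            rec.info["SVLEN"] = c.length
            g = by_id.get(c.id)
            if g is not None:
                rec.info["GTCLASS"] = g.label
                for i, cls in enumerate(CLASS_ORDER):
                    rec.info[f"P{cls}"] = float(g.probabilities[i])
            vf.write(rec)


def trace_report(
    model: MRVMClassifier,
    csv_path: str | Path | None = None,
    plot_path: str | Path | None = None,
) -> pd.DataFrame:
    """Relevance-vector count per training iteration, as a table (and plot)."""
    trace = model.trace_
    if trace is None or len(trace) == 0:
        raise ValueError("model has an empty training trace")
    if csv_path is not None:
        trace.to_csv(csv_path, index=False)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(trace["iteration"], trace["n_relevance_vectors"])
        ax.set_xlabel("iteration")
        ax.set_ylabel("relevance vectors")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return trace
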