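"""End-to-end analyses on a simulated study: replicate-consensus
classification against ground truth, knockout fold-change (theta) recovery,
and pausing-index recovery.

These are the package's standard recipes; each simulates the relevant
replicate tracks, runs the generic pipeline operations, and compares the
result with the generator's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import call_peaks, consensus_call, rpm_normalize, spike_scale_cuttag
from .occupancy import GroupComparison, fold_change, promoter_signal
from .pausing import pausing_index, replicate_average
from .simulate import SimulatedStudy, simulate_tracks

__all__ = [
    "consensus_status",
    "classification_agreement",
    "theta_recovery",
    "pausing_recovery",
    "mean_promoter_signal",
]


def _replicate_peaks(study: SimulatedStudy, assay: str, stage: str,
                     condition: str = "control", fdr: float = 0.01,
                     background_assay: str | None = None) -> list:
    per_rep = []
    for rep in range(1, study.design.replicates + 1):
        track, _ = simulate_tracks(study, assay, stage, condition, rep)
        background = None
        if background_assay is not None:
            background, _ = simulate_tracks(study, background_assay, stage,
                                            condition, rep)
        per_rep.append(call_peaks(track, background=background, fdr=fdr))
    return per_rep


def consensus_status(study: SimulatedStudy, assay: str, stage: str = "SpG",
                     condition: str = "control", fdr: float = 0.01,
                     background_assay: str | None = None,
                     half_width: int = 2000, min_reps: int = 2) -> pd.Series:
    """Per-gene replicate-consensus call for one assay (peak within
    +/-2 kb of a TSS in >= 2 of the replicates)."""
    per_rep = _replicate_peaks(study, assay, stage, condition, fdr,
                               background_assay)
    calls = {
        g.gene_id: consensus_call(g, per_rep, half_width, min_reps).status
        for g in study.genes
    }
    return pd.Series(calls, name=f"{assay}_{stage}")


@dataclass
class ClassificationAgreement:
    poised: float
    accessible: float
    bound: float
    n_label_genes: int

    @property
    def overall(self) -> float:
        return float(np.mean([self.poised, self.accessible, self.bound]))


def classification_agreement(study: SimulatedStudy,
                             fdr: float = 0.01) -> ClassificationAgreement:
    """Fraction of genes whose poised / accessible / bound consensus calls
    match the ground truth.

    Poised (engaged Pol II) and accessible (open chromatin) labels are
    evaluated over meiosis-I and spermiogenesis genes; the factor-bound
    label over poised genes.
    """
    truth = study.truth
    label_ids = truth.index[truth["category"].isin(["meiosis_I", "spermiogenesis"])]
    poised_ids = truth.index[truth["poised"]]

    poised_calls = consensus_status(study, "proseq", "SpG", fdr=fdr)
    atac_calls = consensus_status(study, "atac", "SpG", fdr=fdr)
    bound_calls = consensus_status(study, "cutrun", "SpG", fdr=fdr,
                                   background_assay="igg")

    poised_agree = float((poised_calls[label_ids] == truth.loc[label_ids, "poised"]).mean())
    access_agree = float((atac_calls[label_ids] == truth.loc[label_ids, "poised"]).mean())
    bound_agree = float((bound_calls[poised_ids] == truth.loc[poised_ids, "bound"]).mean())
    return ClassificationAgreement(poised_agree, access_agree, bound_agree,
                                   n_label_genes=len(label_ids))


def mean_promoter_signal(study: SimulatedStudy, assay: str, stage: str,
                         condition: str, genes=None, half_width: int = 200,
                         normalization: str = "rpm") -> pd.Series:
    """Replicate-averaged normalized promoter signal (+/- half_width of the TSS).

    ``normalization="rpm"`` scales per million mapped reads; ``"spike"``
    scales by the constant-material spike-in (needed for between-condition
    comparisons, where per-million scaling would absorb a global loss of
    signal into the normalization).
    """
    genes = study.genes if genes is None else genes
    per_rep = []
    for rep in range(1, study.design.replicates + 1):
        track, stats = simulate_tracks(study, assay, stage, condition, rep)
        if normalization == "rpm":
            norm = rpm_normalize(track, stats)
        elif normalization == "spike":
            norm = spike_scale_cuttag(track, stats)
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
        per_rep.append({
            g.gene_id: promoter_signal(norm, g, half_width).value for g in genes
        })
    frames = pd.DataFrame(per_rep)
    return frames.mean(axis=0)


@dataclass
class ThetaRecovery:
    comparison: GroupComparison
    median_bound: float
    median_unbound: float | None
    by_quartile: dict[str, float]
    n_bound: int


def theta_recovery(study: SimulatedStudy, assay: str = "atac",
                   stage: str = "SpG", half_width: int = 200,
                   eps: float = 0.01) -> ThetaRecovery:
    """Knockout / control promoter fold change at truly bound promoters.

    Simulates control and knockout replicate tracks, averages RPM promoter
    signal per gene across replicates, and summarizes the per-gene ratio
    cko / control at the bound promoters (overall and per occupancy
    quartile); unbound poised promoters give the negative-control median.
    """
    truth = study.truth
    bound_ids = list(truth.index[truth["bound"]])
    if not bound_ids:
        raise ValueError("design has no bound genes")
    genes = {g.gene_id: g for g in study.genes}
    eval_ids = list(truth.index[truth["poised"]]) or bound_ids
    eval_genes = [genes[g] for g in eval_ids]

    control = mean_promoter_signal(study, assay, stage, "control", eval_genes,
                                   half_width, normalization="spike")
    cko = mean_promoter_signal(study, assay, stage, "cko", eval_genes,
                               half_width, normalization="spike")
    comp = fold_change(cko[bound_ids], control[bound_ids], eps=eps)
    unbound_ids = [g for g in eval_ids if g not in set(bound_ids)]
    median_unbound = (
        float(((cko[unbound_ids] + eps) / (control[unbound_ids] + eps)).median())
        if unbound_ids else None
    )
    by_quartile = {}
    for q in ("Q1", "Q2Q3", "Q4"):
        ids = [g for g in bound_ids if truth.at[g, "quartile"] == q]
        if ids:
            by_quartile[q] = float(((cko[ids] + eps) / (control[ids] + eps)).median())
    return ThetaRecovery(comparison=comp, median_bound=comp.summary,
                         median_unbound=median_unbound,
                         by_quartile=by_quartile, n_bound=len(bound_ids))


@dataclass
class PausingRecovery:
    median_by_stage: dict[str, float]
    ratio: float
    n_genes: int


def pausing_recovery(study: SimulatedStudy, stages=("SpG", "SpI")) -> PausingRecovery:
    """Median replicate-averaged pausing index of poised genes per stage,
    and the first-to-second stage ratio."""
    truth = study.truth
    poised = [g for g in study.genes if truth.at[g.gene_id, "poised"]]
    if not poised:
        raise ValueError("design has no poised genes")
    medians = {}
    for stage in stages:
        per_gene = {g.gene_id: [] for g in poised}
        for rep in range(1, study.design.replicates + 1):
            track, _ = simulate_tracks(study, "proseq", stage, "control", rep)
            for g in poised:
                per_gene[g.gene_id].append(pausing_index(track, g))
        averaged = [replicate_average(v) for v in per_gene.values()]
        defined = [v for v in averaged if v is not None]
        medians[stage] = float(np.median(defined))
    ratio = medians[stages[0]] / medians[stages[1]]
    return PausingRecovery(median_by_stage=medians, ratio=float(ratio),
                           n_genes=len(poised))
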