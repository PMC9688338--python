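"""End-to-end analysis: sensor EEG → source networks → statistics.

``analyze_subject`` runs the single-subject chain (filter chain, common
average reference, GFP spike detection, epoching, noise covariance, sLORETA,
imaginary coherence); ``run_cohort`` applies it to a whole (synthetic)
cohort and performs the group-level steps: paired NBS between states,
weighted modified networks, characteristic path length / clustering /
small-world propensity per subject, the paired statistical protocol, and
IVI hub identification on the group-level spike-wave network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import connectivity, graphmetrics, influence, nbs, preprocess, srcloc
from .connectivity import DEFAULT_FREQS, ConnectivityTensor
from .srcloc import LeadField
from .statprotocol import StatReport, paired_state_comparison
from .syndata import SynthConfig, synthesize_cohort

__all__ = [
    "SubjectResult",
    "CohortResult",
    "analyze_subject",
    "run_cohort",
    "match_events",
]


@dataclass
class SubjectResult:
    events: preprocess.EventList
    gsw_epochs: preprocess.EpochSet
    rs_epochs: preprocess.EpochSet
    imcoh_gsw: np.ndarray  # (n_freqs, nodes, nodes)
    imcoh_rs: np.ndarray


@dataclass
class CohortResult:
    tensor_gsw: ConnectivityTensor
    tensor_rs: ConnectivityTensor
    nbs_results: dict[int, nbs.NBSResult]
    adjacency: dict[int, np.ndarray]
    metrics: pd.DataFrame                  # subject, frequency, state, L, C
    path_length_tests: dict[int, StatReport]
    ivi: dict[int, influence.IVIResult]
    swp: dict[int, list[graphmetrics.SWPResult]] = field(default_factory=dict)


def analyze_subject(
    rec: preprocess.SensorRecording,
    lead_field: LeadField,
    freqs: tuple[int, ...] = DEFAULT_FREQS,
    min_prominence: float = 10.0,
    refractory: float = 0.1,
    epoch_half: float = 2.0,
    seed: int = 0,
) -> SubjectResult:
    """Single-subject chain from raw sensors to per-state ImCoh matrices."""
    filtered = preprocess.common_average_reference(
        preprocess.apply_filter_chain(rec))
    gfp = preprocess.global_field_power(filtered)
    events = preprocess.detect_spike_events(gfp, min_prominence, refractory)
    gsw = preprocess.extract_epochs(filtered, events, pre=epoch_half,
                                    post=epoch_half)
    rs = preprocess.select_rs_epochs(filtered, events, n=gsw.n_epochs,
                                     dur=2 * epoch_half, seed=seed)
    ncov = srcloc.estimate_noise_covariance(rs.data)
    lf_car = srcloc.average_reference_gain(lead_field)

    def _source_epochs(epochs: preprocess.EpochSet) -> np.ndarray:
        out = [srcloc.sloreta_solve(lf_car, ncov, ep).activity
               for ep in epochs.data]
        n_src = lead_field.n_sources
        n_samp = epochs.data.shape[-1] if epochs.n_epochs else 0
        return (np.stack(out) if out
                else np.empty((0, n_src, n_samp)))

    src_gsw = _source_epochs(gsw)
    src_rs = _source_epochs(rs)
    imcoh_gsw = connectivity.imaginary_coherence_matrix(src_gsw, rec.fs, freqs)
    imcoh_rs = connectivity.imaginary_coherence_matrix(src_rs, rec.fs, freqs)
    return SubjectResult(events, gsw, rs, imcoh_gsw, imcoh_rs)


def run_cohort(
    cfg: SynthConfig,
    lead_field: LeadField | None = None,
    freqs: tuple[int, ...] = DEFAULT_FREQS,
    nbs_freqs: tuple[int, ...] | None = None,
    nbs_threshold: float = 1.0,
    strict_threshold: float = 3.5,
    n_perm: int = 500,
    alpha: float = 0.05,
    min_prominence: float = 10.0,
    compute_swp: bool = False,
    n_null: int = 10,
) -> CohortResult:
    """Synthesize a cohort and run the full group analysis.

    ``nbs_freqs`` defaults to the spike-wave repetition frequency of the
    configuration.  Per-subject weighted networks are the |ImCoh| matrices
    masked by the NBS adjacency (GSW > RS, lenient threshold
    ``nbs_threshold``); path length and clustering are computed on them per
    state, and the paired protocol tests the GSW-vs-RS path-length
    difference.  Hub identification (IVI) runs on the group-mean GSW
    network masked by a second, strict NBS pass (``strict_threshold``),
    which isolates the strongest state differences and keeps the binarized
    centralities from saturating on the dense lenient graph.
    """
    recordings, truths, lead_field = synthesize_cohort(cfg, lead_field)
    if nbs_freqs is None:
        nbs_freqs = (int(round(cfg.f_sw)),)

    slices_gsw, slices_rs = [], []
    for si, rec in enumerate(recordings):
        res = analyze_subject(rec, lead_field, freqs,
                              min_prominence=min_prominence,
                              epoch_half=cfg.epoch_len / 2,
                              seed=cfg.seed * 1000 + si)
        slices_gsw.append(res.imcoh_gsw)
        slices_rs.append(res.imcoh_rs)
    labels = list(lead_field.source_ids)
    tensor_gsw = ConnectivityTensor(np.stack(slices_gsw), tuple(freqs),
                                    "GSW", labels)
    tensor_rs = ConnectivityTensor(np.stack(slices_rs), tuple(freqs),
                                   "RS", labels)

    nbs_results: dict[int, nbs.NBSResult] = {}
    adjacency: dict[int, np.ndarray] = {}
    rows = []
    tests: dict[int, StatReport] = {}
    ivi_results: dict[int, influence.IVIResult] = {}
    swp_results: dict[int, list[graphmetrics.SWPResult]] = {}
    import warnings as _warnings

    for f in nbs_freqs:
        fi = tuple(freqs).index(f)
        abs_gsw = np.abs(tensor_gsw.values[:, fi])
        abs_rs = np.abs(tensor_rs.values[:, fi])
        res = nbs.nbs_paired(abs_gsw, abs_rs, threshold=nbs_threshold,
                             n_perm=n_perm, seed=cfg.seed + f, tail="A>B")
        nbs_results[f] = res
        adj = nbs.significant_adjacency(res, alpha)
        adjacency[f] = adj

        for si in range(len(recordings)):
            for state, mats in (("GSW", abs_gsw), ("RS", abs_rs)):
                w = nbs.apply_adjacency_weights(adj, mats[si])
                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore")
                    L = (graphmetrics.characteristic_path_length(w)
                         if np.any(w.weights > 0) else np.nan)
                C = graphmetrics.mean_clustering_coefficient(w)
                rows.append((si, f, state, L, C))

        table = pd.DataFrame(rows, columns=["subject", "frequency", "state",
                                            "L", "C"])
        tab_f = table[table["frequency"] == f].rename(columns={"L": "value"})
        if tab_f["value"].notna().all():
            tests[f] = paired_state_comparison(
                tab_f[["subject", "frequency", "state", "value"]], f,
                n_comparisons=len(freqs))

        strict = nbs.nbs_paired(abs_gsw, abs_rs, threshold=strict_threshold,
                                n_perm=n_perm, seed=cfg.seed + 100 + f,
                                tail="A>B")
        adj_strict = nbs.significant_adjacency(strict, alpha)
        group_gsw = nbs.apply_adjacency_weights(adj_strict,
                                                np.mean(abs_gsw, axis=0))
        group_gsw.node_labels = labels
        if np.any(group_gsw.weights > 0):
            tab = influence.centrality_suite(group_gsw)
            ivi_results[f] = influence.integrated_value_of_influence(tab)
        if compute_swp:
            per_subject = []
            for si in range(len(recordings)):
                w = nbs.apply_adjacency_weights(adj, abs_gsw[si])
                if np.any(w.weights > 0):
                    with _warnings.catch_warnings():
                        _warnings.simplefilter("ignore")
                        per_subject.append(graphmetrics.small_world_propensity(
                            w, n_null=n_null, seed=cfg.seed + si))
            swp_results[f] = per_subject

    metrics = pd.DataFrame(rows, columns=["subject", "frequency", "state",
                                          "L", "C"])
    return CohortResult(tensor_gsw, tensor_rs, nbs_results, adjacency,
                        metrics, tests, ivi_results, swp_results)


def match_events(
    detected: np.ndarray | preprocess.EventList,
    truth: np.ndarray,
    tol: int = 8,
) -> tuple[float, float]:
    """(sensitivity, precision) of detected vs planted event samples.

    Each truth event may claim at most one detection within ``tol`` samples.
    """
    det = np.asarray(list(detected), dtype=int)
    tru = np.asarray(truth, dtype=int)
    if tru.size == 0:
        return (1.0, 1.0 if det.size == 0 else 0.0)
    used = np.zeros(det.size, dtype=bool)
    hits = 0
    for t in tru:
        if det.size == 0:
            break
        d = np.abs(det - t)
        d[used] = tol + 1
        j = int(np.argmin(d))
        if d[j] <= tol:
            used[j] = True
            hits += 1
    sens = hits / tru.size
    prec = hits / det.size if det.size else 1.0
    return float(sens), float(prec)
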