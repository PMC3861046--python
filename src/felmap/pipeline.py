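"""End-to-end orchestration: state comparison and collective analysis.

``run_state_comparison`` takes replicate dihedral ensembles for up to three
ligand states and chains the full sequence comparison: replicate gating
(DATA sets), state-average PDFs, pairwise dissimilarity on DATA
intersections, the four-pattern specificity classification, and the
residue/subdomain network of the classified angles.
``classify_network`` runs the classification-only tail on a bare
similarity matrix (fixture mode).  ``run_collective_analysis`` chains
subset dPCA, the cosine-content sampling check, the 2D free-energy
surface, minima, the chained minimum-energy path, and per-step dihedral
profiles.  Reports are plain dicts, serializable to JSON.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import dpca as _dpca
from . import fes as _fes
from .cgda import DihedralSeries
from .fep import (CONVERGENCE_THRESHOLD, AngularPDF, average_pdf,
                  estimate_pdf, similarity_H)
from .statecompare import (INFLUENCE_THRESHOLD, SimilarityMatrix,
                           classify_specificity, dissimilarity_bins,
                           locate_network, residues_of_angles)
from .trajio import SubdomainMap, dnak_subdomain_map

logger = logging.getLogger("felmap")

__all__ = ["AnalysisConfig", "run_state_comparison", "classify_network",
           "run_collective_analysis"]


@dataclass
class AnalysisConfig:
    """Thresholds and binning for the end-to-end analyses."""

    gate_threshold: float = CONVERGENCE_THRESHOLD
    influence_threshold: float = INFLUENCE_THRESHOLD
    strong_threshold: float = 0.7
    n_angular_bins: int = 72
    fes_bin: float = 0.1
    temperature: float = 300.0
    minima_depth: float = 3.0
    kernel: str = "bhattacharyya"
    subdomains: SubdomainMap | None = None
    seed: int = 0

    def thresholds(self) -> dict[str, float]:
        return {"gate": self.gate_threshold,
                "influenced": self.influence_threshold,
                "strong": self.strong_threshold}


def _per_angle_pdfs(series: DihedralSeries, n_bins: int) -> dict[int, AngularPDF]:
    return {int(i): estimate_pdf(series.column(int(i)), n_bins=n_bins)
            for i in series.angle_indices}


def run_state_comparison(state_runs: dict[str, list[DihedralSeries]],
                         cfg: AnalysisConfig | None = None) -> dict:
    """Gate replicates, compare states on DATA intersections, classify.

    ``state_runs`` maps a state label (e.g. 'APO') to its replicate
    dihedral ensembles (>= 2 per state for gating).
    """
    cfg = cfg or AnalysisConfig()
    report: dict = {"thresholds": cfg.thresholds(), "states": {},
                    "comparisons": {}, "network": None}

    if len(state_runs) < 2:
        report["skipped"] = "fewer than two states supplied; comparison skipped"
        logger.info(report["skipped"])
        return report

    data_sets: dict[str, set[int]] = {}
    avg_pdfs: dict[str, dict[int, AngularPDF]] = {}
    for state, runs in state_runs.items():
        if len(runs) < 2:
            raise ValueError(f"state {state!r} needs >= 2 replicate runs")
        pdfs = [_per_angle_pdfs(r, cfg.n_angular_bins) for r in runs[:2]]
        angles = [int(i) for i in runs[0].angle_indices]
        h_rep = {i: similarity_H(pdfs[0][i], pdfs[1][i], kernel=cfg.kernel)
                 for i in angles}
        data = {i for i, h in h_rep.items() if h > cfg.gate_threshold}
        data_sets[state] = data
        avg_pdfs[state] = {i: average_pdf(pdfs[0][i], pdfs[1][i]) for i in data}
        report["states"][state] = {
            "n_total": len(angles), "n_pass": len(data),
            "data_angles": sorted(data),
            "replicate_H": {str(i): h_rep[i] for i in angles},
        }

    states = list(state_runs)
    pair_h: dict[tuple[str, str], dict[int, float]] = {}
    for a_i, s1 in enumerate(states):
        for s2 in states[a_i + 1:]:
            common = sorted(data_sets[s1] & data_sets[s2])
            h = {i: similarity_H(avg_pdfs[s1][i], avg_pdfs[s2][i],
                                 kernel=cfg.kernel) for i in common}
            pair_h[(s1, s2)] = h
            bins = dissimilarity_bins([h[i] for i in common])
            report["comparisons"][f"{s1}/{s2}"] = {
                "n_common": len(common),
                "H": {str(i): h[i] for i in common},
                "bins": {str(i): b for i, b in zip(common, bins)},
                "counts": {b: int((bins == b).sum())
                           for b in ("weak", "significant", "strong")},
            }

    if set(states) >= {"APO", "ADP", "ATP"}:
        triple = sorted(set.intersection(*(data_sets[s]
                                           for s in ("APO", "ADP", "ATP"))))
        labels = {("APO", "ADP"): "APO/ADP", ("APO", "ATP"): "APO/ATP",
                  ("ADP", "ATP"): "ADP/ATP"}
        cols = {}
        for key, lab in labels.items():
            h = pair_h.get(key) or pair_h.get(key[::-1])
            cols[lab] = np.array([h[i] for i in triple])
        matrix = SimilarityMatrix(np.asarray(triple, int), cols)
        report["network"] = classify_network(matrix,
                                             cfg.subdomains or dnak_subdomain_map())
    return report


def classify_network(matrix: SimilarityMatrix,
                     subdomains: SubdomainMap | None = None,
                     use_flags: bool = False) -> dict:
    """Specificity classification plus residue/subdomain network summary."""
    subdomains = subdomains or dnak_subdomain_map()
    assignment = classify_specificity(matrix, use_flags=use_flags)
    classified = [i for i, c in assignment.categories.items() if c != "NONE"]
    network = residues_of_angles(classified)
    return {
        "categories": {str(i): c for i, c in sorted(assignment.categories.items())},
        "category_counts": assignment.counts,
        "n_classified": len(classified),
        "n_residues": network.n_residues,
        "residues": network.residues.tolist(),
        "subdomain_counts": locate_network(classified, subdomains),
    }


def run_collective_analysis(series: DihedralSeries, subset,
                            cfg: AnalysisConfig | None = None) -> dict:
    """Subset dPCA -> FES -> minima -> chained PME -> step profiles."""
    cfg = cfg or AnalysisConfig()
    emb = _dpca.embed(series, subset)
    model = _dpca.fit_dpca(emb)
    if model.total_variance < 1e-12:
        return {"degenerate": True,
                "reason": "constant trajectory: no collective modes",
                "eigenvalues": model.eigenvalues.tolist()}
    pc1 = _dpca.project(emb, model, 1)
    pc2 = _dpca.project(emb, model, 2)
    cc1 = _dpca.cosine_content(pc1)
    cc2 = _dpca.cosine_content(pc2)
    if cc1 > 0.5:
        logger.warning(
            "cosine content of dPC1 is %.2f (> 0.5): sampling is "
            "random-walk-like and FES basins may be artifacts", cc1)

    surface = _fes.build_fes(pc1, pc2, bin=cfg.fes_bin,
                             temperature=cfg.temperature)
    minima = _fes.find_minima(surface, depth=cfg.minima_depth)
    report = {
        "eigenvalue_fractions_percent":
            (100.0 * model.variance_fractions()).tolist(),
        "cosine_content": {"dPC1": cc1, "dPC2": cc2},
        "influences": model.influences[:, :2].T.tolist(),
        "n_minima": len(minima),
        "minima": [{"label": m.label, "bin": list(m.bin), "V": m.value,
                    "first_visit_ps": m.first_visit_time} for m in minima],
    }
    if len(minima) >= 2:
        path = _fes.chain_pme(surface, list(minima))
        profiles = _fes.step_profiles(surface, path, series, subset,
                                      n_bins=cfg.n_angular_bins)
        report["pme"] = {
            "n_steps": path.n_steps,
            "steps": [list(s) for s in path.steps],
            "V": path.values.tolist(),
            "minima_steps": path.leg_boundaries,
            "saddle_steps": path.saddle_indices,
            "barriers": path.barriers(),
            "step_frames": [int(f.size) for f in path.frame_lists],
            "step_first_visit_ps": [p.first_visit_time for p in profiles],
            "step_most_probable": [
                {str(i): v for i, v in p.most_probable.items()}
                for p in profiles],
        }
    return report
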