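"""Comparative analysis pipeline: unbound structure vs. complex.

Runs the elastic-network, communication, structure-network and frustration
stages on two structures (typically a free protein and the same protein bound
to a partner), restricts the per-residue quantities to the residues the two
inputs share, and reports signed differences with the fixed convention
(complex − unbound). Differences are computed once, from the two mapped
arrays, so a self-comparison yields exact zeros.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import communication, enm, frustration, psn
from .structure_io import CoarseStructure, StructureEnsemble

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

#: Default analysis parameters: r_c 7.0 Å, 20 low-frequency modes, 20 Å
#: minimum communicator separation, I_min 3.0%, k = 3 cliques, 0.75
#: persistence, 1000 decoys, 5 Å frustration-density radius. A run with zero
#: overrides reproduces the reference settings of the analysis.
DEFAULT_PARAMS = {
    "cutoff_rc": enm.DEFAULT_CUTOFF_A,
    "n_modes": enm.MODE_PRESETS["default"],
    "min_separation_A": communication.DEFAULT_MIN_SEPARATION_A,
    "cp_quantile": communication.DEFAULT_CP_QUANTILE,
    "cp_threshold": None,
    "i_min": psn.DEFAULT_I_MIN,
    "k": psn.DEFAULT_K,
    "overlap_rule": psn.DEFAULT_OVERLAP_RULE,
    "min_persistence": psn.DEFAULT_MIN_PERSISTENCE,
    "psn_normalization": "default",
    "n_decoys": frustration.DEFAULT_N_DECOYS,
    "contact_cutoff_A": frustration.DEFAULT_CONTACT_CUTOFF_A,
    "density_radius_A": frustration.DEFAULT_DENSITY_RADIUS_A,
    "seed": 0,
}

ANALYSES = ("gnm", "cp", "psn", "frustration")


class MappingError(ValueError):
    """Raised when two structures share no residues."""


@dataclass
class ResidueMapping:
    """Correspondence between residues of two structures.

    ``pairs[k] = (ia, ib)`` matches serial index ``ia`` in structure *a* with
    ``ib`` in *b*; matching is on (chain, author number, insertion code,
    residue type). Unmatched residues of each side are listed.
    """

    pairs: list[tuple[int, int]]
    unmatched_a: list[int]
    unmatched_b: list[int]

    @property
    def n_common(self) -> int:
        return len(self.pairs)

    def index_a(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=int)

    def index_b(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=int)


@dataclass
class ComparisonReport:
    """Differential report between an unbound structure (a) and a complex (b).

    All deltas follow the (complex − unbound) sign convention and live on the
    common residue mapping.
    """

    mapping: ResidueMapping
    parameters: dict
    mobility_delta: np.ndarray | None = None
    correlation_delta: np.ndarray | None = None
    communicators_gained: list[tuple[int, int]] = field(default_factory=list)
    communicators_lost: list[tuple[int, int]] = field(default_factory=list)
    cluster_count_delta: int | None = None
    psn_counts: dict | None = None
    frustration_fractions: dict | None = None
    schema_version: int = REPORT_SCHEMA_VERSION

    def to_json_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "parameters": {k: v for k, v in self.parameters.items()},
            "n_common_residues": self.mapping.n_common,
            "n_unmatched_a": len(self.mapping.unmatched_a),
            "n_unmatched_b": len(self.mapping.unmatched_b),
            "mobility_delta": (None if self.mobility_delta is None
                               else self.mobility_delta.tolist()),
            "communicators_gained": [list(p) for p in self.communicators_gained],
            "communicators_lost": [list(p) for p in self.communicators_lost],
            "cluster_count_delta": self.cluster_count_delta,
            "psn_counts": self.psn_counts,
            "frustration_fractions": self.frustration_fractions,
        }


def map_common_residues(a: CoarseStructure,
                        b: CoarseStructure) -> ResidueMapping:
    """Match residues of two structures on (chain, number, icode, type)."""
    by_identity_b = {res.identity: res.serial_index for res in b.residues}
    pairs = []
    unmatched_a = []
    matched_b = set()
    for res in a.residues:
        ib = by_identity_b.get(res.identity)
        if ib is None:
            unmatched_a.append(res.serial_index)
        else:
            pairs.append((res.serial_index, ib))
            matched_b.add(ib)
    unmatched_b = [res.serial_index for res in b.residues
                   if res.serial_index not in matched_b]
    if not pairs:
        raise MappingError("structures share no residues "
                           "(chain/author-number/type intersection is empty)")
    return ResidueMapping(pairs=pairs, unmatched_a=unmatched_a,
                          unmatched_b=unmatched_b)


def _mobility(structure: CoarseStructure, params: dict) -> np.ndarray:
    network = enm.build_network(structure, cutoff_rc=params["cutoff_rc"])
    spectrum = enm.decompose(network)
    return enm.mean_square_fluctuations(spectrum).msf


def _correlations(structure: CoarseStructure, params: dict) -> np.ndarray:
    network = enm.build_network(structure, cutoff_rc=params["cutoff_rc"])
    spectrum = enm.decompose(network)
    available = spectrum.n_nodes - spectrum.n_zero_modes
    n_modes = min(params["n_modes"], available)
    modes = spectrum.slowest_modes(n_modes)
    return enm.cross_correlations(spectrum, modes=modes).normalized


def _communicator_pairs(structure: CoarseStructure,
                        params: dict) -> tuple[set, int]:
    network = enm.build_network(structure, cutoff_rc=params["cutoff_rc"])
    commute = communication.commute_times(network)
    report = communication.effective_pairs(
        commute, structure,
        threshold=params["cp_threshold"],
        quantile=params["cp_quantile"],
        min_separation_A=params["min_separation_A"])
    pairs = {(i, j) for i, j, *_ in report.pairs}
    return pairs, len(report.clusters)


def compare(
    a: CoarseStructure | StructureEnsemble,
    b: CoarseStructure | StructureEnsemble,
    analyses=("gnm",),
    params: dict | None = None,
) -> ComparisonReport:
    """Run selected analyses on both inputs and report (b − a) differences.

    ``a`` is the unbound reference, ``b`` the complex. Per-residue and
    per-matrix deltas are restricted to the common residue mapping. PSN and
    frustration stages report per-structure summaries side by side (counts
    and category fractions), since those quantities are not per-residue.
    Ensembles are accepted for the psn stage (persistence analysis); other
    stages use the first frame.
    """
    merged = dict(DEFAULT_PARAMS)
    if params:
        unknown = set(params) - set(DEFAULT_PARAMS)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        merged.update(params)
    unknown_analyses = set(analyses) - set(ANALYSES)
    if unknown_analyses:
        raise ValueError(f"unknown analyses: {sorted(unknown_analyses)}")

    struct_a = a.frames[0] if isinstance(a, StructureEnsemble) else a
    struct_b = b.frames[0] if isinstance(b, StructureEnsemble) else b
    mapping = map_common_residues(struct_a, struct_b)
    report = ComparisonReport(mapping=mapping, parameters=merged)
    ia, ib = mapping.index_a(), mapping.index_b()

    if "gnm" in analyses:
        try:
            msf_a = _mobility(struct_a, merged)[ia]
            msf_b = _mobility(struct_b, merged)[ib]
            report.mobility_delta = msf_b - msf_a
            corr_a = _correlations(struct_a, merged)[np.ix_(ia, ia)]
            corr_b = _correlations(struct_b, merged)[np.ix_(ib, ib)]
            report.correlation_delta = corr_b - corr_a
        except Exception as exc:
            raise RuntimeError(f"gnm stage failed: {exc}") from exc

    if "cp" in analyses:
        try:
            pairs_a, n_clusters_a = _communicator_pairs(struct_a, merged)
            pairs_b, n_clusters_b = _communicator_pairs(struct_b, merged)
            # Compare on the common mapping (serial indices of structure a).
            to_a = {pb: pa for pa, pb in mapping.pairs}
            pairs_b_mapped = {(to_a[i], to_a[j]) for i, j in pairs_b
                              if i in to_a and j in to_a}
            pairs_b_mapped = {(min(p), max(p)) for p in pairs_b_mapped}
            pairs_a = {(min(p), max(p)) for p in pairs_a
                       if p[0] in dict(mapping.pairs)
                       and p[1] in dict(mapping.pairs)}
            report.communicators_gained = sorted(pairs_b_mapped - pairs_a)
            report.communicators_lost = sorted(pairs_a - pairs_b_mapped)
            report.cluster_count_delta = n_clusters_b - n_clusters_a
        except Exception as exc:
            raise RuntimeError(f"cp stage failed: {exc}") from exc

    if "psn" in analyses:
        try:
            table = psn.count_summary(
                {"unbound": a, "complex": b},
                k=merged["k"], overlap_rule=merged["overlap_rule"],
                i_min=merged["i_min"],
                min_fraction=merged["min_persistence"],
                normalization=merged["psn_normalization"])
            report.psn_counts = table.to_dict(orient="index")
        except Exception as exc:
            raise RuntimeError(f"psn stage failed: {exc}") from exc

    if "frustration" in analyses:
        try:
            fractions = {}
            for name, structure in (("unbound", struct_a),
                                    ("complex", struct_b)):
                profile = frustration.frustration_profile(
                    structure, n_decoys=merged["n_decoys"],
                    rng_seed=merged["seed"],
                    contact_cutoff_A=merged["contact_cutoff_A"])
                fractions[name] = profile.category_fractions()
            report.frustration_fractions = fractions
        except Exception as exc:
            raise RuntimeError(f"frustration stage failed: {exc}") from exc

    return report


# ---------------------------------------------------------------------------
# Config-file runs
# ---------------------------------------------------------------------------

CONFIG_KEYS = {"inputs", "analyses", "parameters", "output_dir", "seed",
               "label"}


def run_config(config_path, output_dir=None) -> Path:
    """Execute a declarative comparison run from a YAML config file.

    The config declares ``inputs`` (labels → PDB paths; ``unbound`` and
    ``complex``), the ``analyses`` to run, parameter overrides, a ``seed``,
    and an ``output_dir``. The run directory receives the JSON report, TSV
    difference tables, and a log of every parameter and seed used, so a rerun
    with the same config is byte-identical.
    """
    import yaml

    from .structure_io import read_structure_file

    with open(config_path) as fh:
        config = yaml.safe_load(fh) or {}
    unknown = set(config) - CONFIG_KEYS
    if unknown:
        raise KeyError(f"unknown config key(s): {sorted(unknown)}")
    if "inputs" not in config:
        raise KeyError("config is missing required key: 'inputs'")
    inputs = config["inputs"]
    for role in ("unbound", "complex"):
        if role not in inputs:
            raise KeyError(f"config 'inputs' is missing required key: "
                           f"'{role}'")
    analyses = config.get("analyses", ["gnm"])
    params = dict(config.get("parameters") or {})
    if "seed" in config:
        params["seed"] = int(config["seed"])
    elif "seed" not in params:
        params["seed"] = DEFAULT_PARAMS["seed"]

    out = Path(output_dir or config.get("output_dir") or "allosteer-run")
    out.mkdir(parents=True, exist_ok=True)

    loaded = {}
    for role in ("unbound", "complex"):
        spec = inputs[role]
        path, model = (spec, 1) if isinstance(spec, str) else \
            (spec["path"], spec.get("model", 1))
        loaded[role] = read_structure_file(path, model_index=model,
                                           label=role)

    report = compare(loaded["unbound"], loaded["complex"],
                     analyses=analyses, params=params)
    _write_report(report, out)
    logger.info("run complete: %s", out)
    return out


def _write_report(report: ComparisonReport, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
    if report.mobility_delta is not None:
        np.savetxt(out / "mobility_delta.tsv", report.mobility_delta,
                   delimiter="\t", fmt="%.8g")
    if report.correlation_delta is not None:
        np.savetxt(out / "correlation_delta.tsv", report.correlation_delta,
                   delimiter="\t", fmt="%.8g")
    with open(out / "parameters.log", "w") as fh:
        for key in sorted(report.parameters):
            fh.write(f"{key} = {report.parameters[key]}\n")
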