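"""End-to-end orchestration: filter -> partition -> render -> map -> cluster -> fit.

A :class:`PipelineConfig` (usually read from YAML) names the inputs and the
per-stage settings; :func:`run_pipeline` executes the stages in order,
writing per-stage artifacts plus a run manifest and a machine-readable
``results.json``.  All stochastic stages draw child seeds from the single
global seed, so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .binding import fit_binding, read_binding_tsv
from .contrast import emit_pymol_script, render_contrast_alignment
from .errors import FdrscopeError, PipelineError
from .msa import FilterConfig, filter_fragments, dedupe, read_msa, write_msa
from .partition import Hierarchy, SamplerConfig, patterns_to_tsv, sample_hierarchy
from .cluster_stats import core_clustering, interface_sipris
from .structure import map_seq_to_structure, read_structure

log = logging.getLogger("fdrscope")


@dataclass
class PipelineConfig:
    """Inputs, per-stage settings and the global seed for one run."""

    msa_path: str
    out_dir: str
    msa_format: str = "fasta"
    structure_path: str | None = None
    structure_chain: str = "A"
    partner_chain: str | None = None
    structure_seq_id: str | None = None  # MSA row matching structure_chain
    binding_paths: list[str] = field(default_factory=list)
    binding_hill: bool = False
    filter: FilterConfig = field(default_factory=FilterConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    n_perm: int = 999
    focal_nodes: list[int] | None = None  # None = all non-root nodes
    n_representatives: int = 8
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "filter" in raw:
            raw["filter"] = FilterConfig(**raw["filter"])
        if "sampler" in raw:
            s = dict(raw["sampler"])
            if isinstance(s.get("fixed_shape"), list):
                s["fixed_shape"] = _to_shape(s["fixed_shape"])
            raw["sampler"] = SamplerConfig(**s)
        return cls(**raw)

    def validate(self) -> None:
        if not self.msa_path or not Path(self.msa_path).exists():
            raise PipelineError("validate", f"MSA path missing: {self.msa_path!r}")
        if self.structure_path and not Path(self.structure_path).exists():
            raise PipelineError("validate", f"structure path missing: {self.structure_path!r}")
        for p in self.binding_paths:
            if not Path(p).exists():
                raise PipelineError("validate", f"binding TSV missing: {p!r}")


def _to_shape(nested) -> tuple:
    return tuple(_to_shape(x) for x in nested)


def _child_seeds(global_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(global_seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every configured stage; returns the results dict also written to disk.

    Any stage failure raises :class:`PipelineError` carrying the stage name;
    artifacts of completed stages are retained.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(cfg.seed, 3)  # sampler, sipris, rendering
    results: dict = {"seed": cfg.seed}
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "inputs": {
            "msa": cfg.msa_path,
            "structure": cfg.structure_path,
            "binding": list(cfg.binding_paths),
        },
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except PipelineError:
                raise
            except (FdrscopeError, OSError, KeyError, ValueError) as exc:
                raise PipelineError(name, str(exc)) from exc
            log.info("stage %-10s %.2fs", name, time.perf_counter() - t0)

        return deco

    state: dict = {}

    @stage("filter")
    def _filter():
        msa = read_msa(cfg.msa_path, cfg.msa_format)
        n0 = len(msa)
        msa = filter_fragments(msa, cfg.filter)
        n1 = len(msa)
        msa = dedupe(msa, cfg.filter)
        n2 = len(msa)
        log.info("filter: kept %d / removed %d (fragments %d, redundant %d)",
                 n2, n0 - n2, n0 - n1, n1 - n2)
        write_msa(msa, out / "filtered.fasta")
        state["msa"] = msa
        manifest["stages"]["filter"] = {
            "input": n0, "after_fragments": n1, "kept": n2, "removed": n0 - n2,
        }
        results["filter"] = {"kept": n2, "removed": n0 - n2}

    @stage("partition")
    def _partition():
        msa = state["msa"]
        scfg = cfg.sampler
        scfg = SamplerConfig(**{**scfg.__dict__, "seed": seeds[0]})
        h = sample_hierarchy(msa, scfg)
        state["hierarchy"] = h
        (out / "hierarchy.json").write_text(h.to_json())
        (out / "hierarchy.nwk").write_text(h.to_newick() + "\n")
        (out / "patterns.tsv").write_text(patterns_to_tsv(h))
        non_root = [n for n in h.nodes if n != h.root_id]
        manifest["stages"]["partition"] = {
            "n_nodes": len(h.nodes),
            "n_pattern_positions": sum(len(h.nodes[n].pattern) for n in non_root),
        }
        results["partition"] = {
            "n_nodes": len(h.nodes),
            "nodes": {
                str(n): {
                    "members": len(h.nodes[n].member_ids),
                    "pattern_columns": [p.column for p in h.nodes[n].pattern],
                }
                for n in sorted(h.nodes)
            },
        }

    @stage("render")
    def _render():
        h: Hierarchy = state["hierarchy"]
        focal = cfg.focal_nodes or [n for n in sorted(h.nodes) if n != h.root_id]
        rendered = []
        for nid in focal:
            if nid not in h.nodes or nid == h.root_id:
                continue
            text, html_doc = render_contrast_alignment(
                h, state["msa"], nid, cfg.n_representatives
            )
            (out / f"contrast_node{nid}.txt").write_text(text)
            (out / f"contrast_node{nid}.html").write_text(html_doc)
            rendered.append(nid)
        manifest["stages"]["render"] = {"nodes": rendered}

    if cfg.structure_path:

        @stage("structure")
        def _structure():
            h: Hierarchy = state["hierarchy"]
            s = read_structure(cfg.structure_path)
            seq_id = cfg.structure_seq_id
            if seq_id is None:
                raise PipelineError(
                    "structure", "structure_seq_id is required with a structure input"
                )
            msa = state["msa"]
            rmap = map_seq_to_structure(
                msa[seq_id].ungapped(), s, cfg.structure_chain
            )
            # alignment columns -> ungapped positions of the mapped sequence
            res = msa[seq_id].residues
            pos_at_col = {}
            p = 0
            for c, ch in enumerate(res):
                if ch != "-":
                    p += 1
                    pos_at_col[c + 1] = p
            focal = cfg.focal_nodes or [n for n in sorted(h.nodes) if n != h.root_id]
            sipris_out = {}
            for nid in focal:
                if nid not in h.nodes or nid == h.root_id:
                    continue
                labels = []
                for pat in h.nodes[nid].pattern:
                    pos = pos_at_col.get(pat.column)
                    lab = rmap.to_structure(pos) if pos else None
                    if lab is not None:
                        labels.append(lab)
                if not labels:
                    continue
                (out / f"node{nid}.pml").write_text(
                    emit_pymol_script(labels, cfg.structure_chain, f"node{nid}_pattern")
                )
                entry = {"pattern_residues": labels}
                if cfg.partner_chain:
                    res_if = interface_sipris(
                        s, cfg.structure_chain, cfg.partner_chain, labels,
                        n_perm=cfg.n_perm, seed=seeds[1],
                    )
                    entry["interface"] = {
                        "k_star": res_if.k_star, "x_star": res_if.x_star,
                        "raw_p": res_if.raw_p, "adjusted_p": res_if.adjusted_p,
                    }
                res_core = core_clustering(
                    s, cfg.structure_chain, labels, n_perm=cfg.n_perm, seed=seeds[1]
                )
                entry["core"] = {
                    "k_star": res_core.k_star, "x_star": res_core.x_star,
                    "raw_p": res_core.raw_p, "adjusted_p": res_core.adjusted_p,
                }
                sipris_out[str(nid)] = entry
            (out / "sipris.json").write_text(json.dumps(sipris_out, indent=1, sort_keys=True))
            results["sipris"] = sipris_out
            manifest["stages"]["structure"] = {
                "chain": cfg.structure_chain,
                "coverage": rmap.coverage,
                "nodes_tested": sorted(sipris_out),
            }

    if cfg.binding_paths:

        @stage("binding")
        def _binding():
            fits = {}
            for p in cfg.binding_paths:
                curve = read_binding_tsv(p)
                fit = fit_binding(curve, hill=cfg.binding_hill)
                fits[Path(p).name] = fit.as_dict()
            (out / "binding_fits.json").write_text(json.dumps(fits, indent=1, sort_keys=True))
            results["binding"] = fits
            manifest["stages"]["binding"] = {"n_curves": len(fits)}

    (out / "results.json").write_text(json.dumps(results, indent=1, sort_keys=True))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return results
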