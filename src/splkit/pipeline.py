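"""End-to-end orchestration of the synthetic family survey.

``run_pipeline`` chains the stages — simulate → identify (domain scan) →
expression partitions → co-expression networks (ladder + subsampling null)
→ phylogeny → Ka/Ks → logo — on generated data with known ground truth,
writing every stage's outputs plus a manifest of files with sha256
checksums and the producing stage. Reruns with an identical config and seed
reproduce the checksums bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import domains, expression, logo, molevol, network, phylo
from .simulate import SimulationConfig, named_rng, simulate_codon_pair, simulate_expression, simulate_spl_sequences

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("splkit.pipeline")

_ALL_STAGES = ("simulate", "identify", "expression", "network", "phylo", "kaks", "logo")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Flat declarative configuration for one pipeline run.

    Defaults mirror the surveyed design: a 106-transcript focal family with
    a 2000-transcript unknown background, an alpha ladder from 0.05 down to
    1e-8 by decades, two-thirds subsampling with 20 replicates, and MCL
    inflation 2.0.
    """

    out_dir: str = "splkit_run"
    seed: int = 0
    n_spl: int = 106
    n_background: int = 2000
    n_samples_per_group: Mapping[str, int] = field(
        default_factory=lambda: {f"tissue{i:02d}": 3 for i in range(1, 15)}
    )
    block_spec: Sequence[tuple[int, float]] = field(
        default_factory=lambda: [(20, 0.9), (15, 0.9), (10, 0.85)]
    )
    specificity_spec: Mapping[str, int] = field(
        default_factory=lambda: {"tissue01": 3, "tissue02": 2}
    )
    dropout_rate: float = 0.1
    dispersion: float = 0.5
    expressed_threshold: float = 0.0
    alphas: Sequence[float] = (0.05, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6, 1e-7, 1e-8)
    subsample_fraction: float = 2.0 / 3.0
    subsample_reps: int = 20
    mcl_inflation: float = 2.0
    n_sim_proteins: int = 12
    kaks_omegas: Sequence[float] = (0.2, 0.5, 1.0)
    kaks_n_codons: int = 300
    stages: Sequence[str] = _ALL_STAGES
    plots: bool = False

    def validate(self) -> None:
        self.simulation_config().validate()
        if self.expressed_threshold < 0:
            raise ValueError("expressed_threshold must be >= 0")
        alphas = list(self.alphas)
        if any(a2 >= a1 for a1, a2 in zip(alphas, alphas[1:])):
            raise ValueError("alphas must be strictly decreasing")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if self.subsample_reps < 1:
            raise ValueError("subsample_reps must be >= 1")
        if self.mcl_inflation <= 1:
            raise ValueError("mcl_inflation must exceed 1")
        if self.n_sim_proteins < 1:
            raise ValueError("n_sim_proteins must be >= 1")
        if any(w <= 0 for w in self.kaks_omegas):
            raise ValueError("kaks_omegas must be positive")
        if self.kaks_n_codons < 50:
            raise ValueError("kaks_n_codons must be >= 50")
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            n_spl=self.n_spl,
            n_background=self.n_background,
            n_samples_per_group=dict(self.n_samples_per_group),
            block_spec=[tuple(b) for b in self.block_spec],
            specificity_spec=dict(self.specificity_spec),
            dropout_rate=self.dropout_rate,
            dispersion=self.dispersion,
            seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_fasta(records: Sequence[tuple[str, str]], path: Path) -> None:
    with path.open("w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the manifest dictionary.

    Stage outputs land under ``config.out_dir``. A failing stage raises
    :class:`PipelineError` naming the stage; files already written stay on
    disk and are listed in a partial manifest saved before the abort.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enabled = list(config.stages)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": []}
    state: dict = {}

    def record(stage: str, path: Path, params: Mapping) -> None:
        manifest["files"].append(
            {
                "file": str(path.relative_to(out)),
                "sha256": _sha256(path),
                "stage": stage,
                "params": {k: str(v) for k, v in params.items()},
            }
        )

    def run_stage(name: str, fn) -> None:
        if name not in enabled:
            return
        t0 = time.perf_counter()
        log.info("stage %s starting (seed=%d)", name, config.seed)
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            (out / "manifest.partial.json").write_text(json.dumps(manifest, indent=2))
            raise PipelineError(name, exc) from exc
        dt = time.perf_counter() - t0
        manifest["stages"][name] = {"seconds": round(dt, 3)}
        log.info("stage %s done in %.2fs", name, dt)

    _producer = {
        "matrix": "simulate",
        "truth": "simulate",
        "proteins": "simulate",
        "coords": "simulate",
        "matches": "identify",
        "spl_ids": "expression",
        "aligned_domains": "phylo",
    }

    def need(dep: str) -> None:
        if dep not in state:
            stage = _producer.get(dep, dep)
            raise RuntimeError(
                f"requires outputs of stage {stage!r}, which is toggled off"
            )

    # --- simulate -----------------------------------------------------------
    def st_simulate() -> None:
        sim_cfg = config.simulation_config()
        matrix, truth = simulate_expression(sim_cfg)
        mpath = out / "expression_matrix.tsv"
        matrix.to_tsv(mpath)
        tpath = out / "ground_truth.tsv"
        truth.to_csv(tpath, sep="\t")
        prot_a, coords_a = simulate_spl_sequences(
            config.n_sim_proteins, "C3HC2HC", seed=config.seed
        )
        prot_b, coords_b = simulate_spl_sequences(
            max(1, config.n_sim_proteins // 2), "C4C2HC", seed=config.seed
        )
        fpath = out / "sim_proteins.fasta"
        _write_fasta(prot_a + prot_b, fpath)
        state.update(
            matrix=matrix,
            truth=truth,
            proteins=prot_a + prot_b,
            coords=coords_a + coords_b,
        )
        params = {"n_spl": config.n_spl, "n_background": config.n_background}
        for p in (mpath, tpath, fpath):
            record("simulate", p, params)

    # --- identify -----------------------------------------------------------
    def st_identify() -> None:
        need("proteins")
        named = [
            (name, m)
            for name, seq in state["proteins"]
            for m in domains.scan_sbp_domain(seq)
        ]
        dpath = out / "domain_matches.tsv"
        dpath.write_text("\n".join(domains.matches_to_tsv_rows(named)) + "\n")
        gpath = out / "domain_matches.gff3"
        gpath.write_text("\n".join(domains.matches_to_gff3_lines(named)) + "\n")
        state["matches"] = named
        for p in (dpath, gpath):
            record("identify", p, {"spec": "default 74-aa template"})

    # --- expression ---------------------------------------------------------
    def st_expression() -> None:
        need("matrix")
        matrix = state["matrix"]
        spl_ids = [t for t in matrix.transcript_ids if not t.startswith("UNK")]
        spl = matrix.subset(spl_ids)
        venn = expression.group_venn(spl, threshold=config.expressed_threshold)
        breadth = expression.tissue_breadth(spl, threshold=config.expressed_threshold)
        summary = {
            "per_group": venn["per_group"],
            "intersection": venn["intersection"],
            "specific": venn["specific"],
            "union": venn["union"],
            "breadth": {
                k: v for k, v in breadth.items() if k != "one_tissue_members"
            },
        }
        epath = out / "expression_summary.json"
        epath.write_text(json.dumps(summary, indent=2, sort_keys=True))
        hpath = out / "heatmap_matrix.tsv"
        expression.heatmap_prep(spl, row_scale=True).to_csv(hpath, sep="\t")
        state["spl_ids"] = spl_ids
        for p in (epath, hpath):
            record("expression", p, {"threshold": config.expressed_threshold})

    # --- network ------------------------------------------------------------
    def st_network() -> None:
        need("matrix")
        need("spl_ids")
        matrix, spl_ids = state["matrix"], state["spl_ids"]
        expressed = sorted(
            set().union(
                *(
                    expression.expressed_set(matrix, g, config.expressed_threshold)
                    for g in matrix.group_labels
                )
            )
            & set(spl_ids)
        )
        bg_pool = [t for t in matrix.transcript_ids if t.startswith("UNK")]
        rng = named_rng(config.seed, "pipeline_controls")
        controls = sorted(rng.choice(bg_pool, size=len(expressed), replace=False))

        alpha0 = config.alphas[0]
        g = network.build_network(matrix, expressed, alpha0)
        network.graph_to_edge_tsv(g, out / "network_edges.tsv")
        clusters, _ = network.mcl_cluster(g, config.mcl_inflation) if g.n_nodes else ([], True)
        cpath = out / "clusters.tsv"
        with cpath.open("w") as fh:
            fh.write("transcript\tcluster\n")
            for ci, members in enumerate(clusters, start=1):
                for t in sorted(members):
                    fh.write(f"{t}\tC{ci}\n")
        ladder = network.pvalue_ladder(matrix, expressed, controls, config.alphas)
        lpath = out / "ladder.tsv"
        ladder.to_frame().to_csv(lpath, sep="\t", index=False)
        sub = network.subsample_null(
            matrix,
            expressed,
            bg_pool,
            config.alphas,
            fraction=config.subsample_fraction,
            reps=config.subsample_reps,
            seed=config.seed,
        )
        spath = out / "subsample_summary.tsv"
        sub.to_frame().to_csv(spath, sep="\t", index=False)
        summary = {
            "alpha": alpha0,
            "nodes": g.n_nodes,
            "edges": g.n_edges,
            "average_connectivity": (
                network.average_connectivity(g) if g.n_nodes else None
            ),
            "n_clusters": len(clusters),
            "cluster_sizes": sorted((len(c) for c in clusters), reverse=True),
        }
        npath = out / "network_summary.json"
        npath.write_text(json.dumps(summary, indent=2, sort_keys=True))
        if config.plots:
            network.plot_ladder(ladder, out / "ladder.png")
            record("network", out / "ladder.png", {})
        params = {"alphas": list(config.alphas), "reps": config.subsample_reps}
        for p in (out / "network_edges.tsv", cpath, lpath, spath, npath):
            record("network", p, params)

    # --- phylo --------------------------------------------------------------
    def st_phylo() -> None:
        need("proteins")
        need("coords")
        aligned = [
            (name, seq[s:e])
            for (name, seq), (s, e) in zip(state["proteins"], state["coords"])
        ]
        apath = out / "sbp_domains.aln.fasta"
        _write_fasta(aligned, apath)
        d, names = phylo.p_distance_matrix(aligned)
        tree = phylo.neighbor_joining(d, names)
        npath = out / "tree.nwk"
        npath.write_text(tree.to_newick() + "\n")
        refs = {
            names[0]: "A",
            next(n for n in names if n.startswith("simC4C2HC")): "B",
        }
        assign = phylo.assign_groups(tree, refs)
        gpath = out / "group_assignments.tsv"
        with gpath.open("w") as fh:
            fh.write("leaf\tgroup\tnearest_ref\tdistance\tambiguous\n")
            for leaf, info in assign.items():
                if leaf == "__monophyly__":
                    continue
                fh.write(
                    f"{leaf}\t{info['group']}\t{info['nearest_ref']}\t"
                    f"{info['distance']:.6g}\t{int(info['ambiguous'])}\n"
                )
        state["aligned_domains"] = aligned
        for p in (apath, npath, gpath):
            record("phylo", p, {"method": "NJ on p-distances"})

    # --- kaks ---------------------------------------------------------------
    def st_kaks() -> None:
        ratios = []
        rows = ["pair\tomega_target\tka\tks\tratio"]
        for i, w in enumerate(config.kaks_omegas):
            s1, s2 = simulate_codon_pair(
                config.kaks_n_codons, w, seed=config.seed + i
            )
            res = molevol.ng86_kaks(s1, s2)
            label = f"pair_omega{w:g}"
            ratios.append((label, res.ratio))
            rows.append(f"{label}\t{w:g}\t{res.ka:.4f}\t{res.ks:.4f}\t{res.ratio:.4f}")
        kpath = out / "kaks.tsv"
        kpath.write_text("\n".join(rows) + "\n")
        summ = molevol.kaks_summary(ratios)
        jpath = out / "kaks_summary.json"
        jpath.write_text(json.dumps(summ, indent=2, sort_keys=True))
        record("kaks", kpath, {"n_codons": config.kaks_n_codons})
        record("kaks", jpath, {})

    # --- logo ---------------------------------------------------------------
    def st_logo() -> None:
        need("aligned_domains")
        profile = logo.column_profile(state["aligned_domains"])
        ic = logo.information_content(profile)
        ipath = out / "information_content.tsv"
        with ipath.open("w") as fh:
            fh.write("column\tbits\n")
            for j, v in enumerate(ic, start=1):
                fh.write(f"{j}\t{v:.4f}\n")
        conserved = logo.conserved_positions(profile, min_fraction=0.9)
        cpath = out / "conserved_positions.tsv"
        with cpath.open("w") as fh:
            fh.write("column\tresidue\n")
            for col, res in conserved:
                fh.write(f"{col}\t{res}\n")
        if config.plots:
            logo.plot_information_profile(profile, out / "logo_profile.png")
            record("logo", out / "logo_profile.png", {})
        for p in (ipath, cpath):
            record("logo", p, {"min_fraction": 0.9})

    for name, fn in (
        ("simulate", st_simulate),
        ("identify", st_identify),
        ("expression", st_expression),
        ("network", st_network),
        ("phylo", st_phylo),
        ("kaks", st_kaks),
        ("logo", st_logo),
    ):
        run_stage(name, fn)

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
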