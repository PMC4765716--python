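"""End-to-end orchestration of the five desk-scale experiments.

The pipeline generates a synthetic structure library, then runs the five
analyses on it — pocket survey, active-site scan, ligand screen, dimer
assembly, DNA assembly — writing TSV/JSON artifacts and a manifest with
a SHA-256 hash per output so a run is reproducible bit-for-bit from its
configuration.  One global seed is expanded into per-stage seeds by a
deterministic derivation (numpy SeedSequence spawning), so stages can be
re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from foldfunc.calibration import TailCalibrator, percentile_cutoff
from foldfunc.generate import (
    GeneratorConfig,
    generate_compact_backbone,
    design_stable_sequence,
    make_dimer_template,
    make_bdna_complex_template,
    make_ligand_pathway_universe,
    write_ligand_tables,
)
from foldfunc.ligands import (
    PocketMatchEvidence,
    binding_statistics,
    call_threshold,
    pathway_enrichment,
    score_ligand,
)
from foldfunc.pockets import (
    background_pocket_scores,
    calibrate_pocket_pvalue,
    compare_pockets,
    detect_pockets,
)
from foldfunc.sites import (
    count_enzyme_classes,
    make_site_template_library,
    scan_target,
    save_template_library,
)
from foldfunc.structure import Structure, write_structure
from foldfunc import complexes as cx
from foldfunc import dna as dn

logger = logging.getLogger("foldfunc")

STAGES = ("generate", "pockets", "sites", "screen", "complexes", "dna", "report")


@dataclasses.dataclass
class ExperimentConfig:
    """Fully serialisable configuration of one pipeline run."""

    seed: int = 1
    outdir: str = "foldfunc_run"
    stages: tuple[str, ...] = STAGES
    # library scale
    n_structures: int = 50
    min_residues: int = 48
    max_residues: int = 80
    mc_steps: int = 3000
    design_steps: int = 4000
    # pockets
    pocket_background_pairs: int = 300
    pocket_p_threshold: float = 0.05
    cluster_threshold: float = 0.55
    # sites
    n_site_templates: int = 6
    site_cutoffs: tuple[float, ...] = (0.5, 0.75, 1.0)
    fold_filter_tm: float = 0.4
    # screen
    n_ligands: int = 300
    n_pathways: int = 10
    n_bits: int = 64
    planted_fold: float = 1.0
    n_template_pockets: int = 5
    top_frac: float = 0.01
    # complexes
    n_complex_templates: int = 5
    n_monomer_pairs: int = 60
    complex_min_tm: float = 0.2      # desk-scale default; scale-dependent
    complex_min_coverage: float = 0.5
    is_background: int = 150
    e_pp_attractive: float = cx.DEFAULT_E_ATTRACTIVE
    e_pp_repulsive: float = cx.DEFAULT_E_REPULSIVE
    is_p_cut: float = 1e-3
    # dna
    n_dna_templates: int = 5
    n_bp: int = 12
    dna_min_tm: float = 0.2          # desk-scale default; scale-dependent
    e_dp_attractive: float = dn.DEFAULT_E_ATTRACTIVE
    e_dp_repulsive: float = dn.DEFAULT_E_REPULSIVE
    itm_cut: float = dn.DEFAULT_ITM_CUT

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["site_cutoffs"] = list(self.site_cutoffs)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "site_cutoffs" in d:
            d["site_cutoffs"] = tuple(d["site_cutoffs"])
        return cls(**d)


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGES))
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(STAGES, children)}


def _sha256(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: pathlib.Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def calibrate_thresholds(backgrounds: Mapping[str, np.ndarray],
                         percentiles: Mapping[str, float],
                         min_n: int = 100) -> dict[str, float]:
    """Map requested background percentiles to score/energy cutoffs."""
    out = {}
    for channel, pct in percentiles.items():
        bg = np.asarray(backgrounds[channel], dtype=float)
        if bg.size < min_n:
            raise ValueError(f"channel {channel}: need >= {min_n} background scores")
        out[channel] = percentile_cutoff(bg, pct)
    return out


class PipelineRun:
    """Mutable state shared across stages of one run."""

    def __init__(self, config: ExperimentConfig):
        self.config = config
        self.outdir = pathlib.Path(config.outdir)
        self.seeds = _stage_seeds(config.seed)
        self.structures: list[Structure] = []
        self.pockets_by_structure: dict[str, list] = {}
        self.pocket_calibrator: TailCalibrator | None = None
        self.site_library = None
        self.universe = None
        self.manifest: dict = {"config": config.to_dict(), "stages": {}}

    # -- helpers ----------------------------------------------------------
    def _record(self, stage: str, outputs: Iterable[pathlib.Path],
                counts: Mapping[str, float]) -> None:
        self.manifest["stages"][stage] = {
            "outputs": {str(p.relative_to(self.outdir)): _sha256(p)
                        for p in sorted(outputs)},
            "counts": {k: (float(v) if isinstance(v, float) else v)
                       for k, v in counts.items()},
        }

    # -- stages -----------------------------------------------------------
    def stage_generate(self) -> None:
        cfg = self.config
        rng = np.random.Generator(np.random.PCG64(self.seeds["generate"]))
        outputs = []
        sdir = self.outdir / "structures"
        sdir.mkdir(parents=True, exist_ok=True)
        for i in range(cfg.n_structures):
            n = int(rng.integers(cfg.min_residues, cfg.max_residues + 1))
            bb_seed = int(rng.integers(2 ** 31))
            backbone = generate_compact_backbone(GeneratorConfig(
                n_residues=n, seed=bb_seed, mc_steps=cfg.mc_steps))
            res = design_stable_sequence(backbone, mc_steps=cfg.design_steps,
                                         seed=int(rng.integers(2 ** 31)))
            s = res.structure
            s.label = f"art{i:04d}"
            self.structures.append(s)
            p = sdir / f"{s.label}.pdb"
            p.write_text(write_structure(s))
            outputs.append(p)
        universe_seed = int(rng.integers(2 ** 31))
        self.universe = make_ligand_pathway_universe(
            cfg.n_ligands, cfg.n_pathways, n_bits=cfg.n_bits,
            planted_fold=cfg.planted_fold, seed=universe_seed,
            n_proteins=cfg.n_structures)
        lig_p = self.outdir / "ligands.tsv"
        path_p = self.outdir / "pathways.tsv"
        write_ligand_tables(self.universe, lig_p, path_p)
        outputs += [lig_p, path_p]
        logger.info("generated %d structures, %d ligands, %d pathways",
                    len(self.structures), cfg.n_ligands, cfg.n_pathways)
        self._record("generate", outputs,
                     {"n_structures": len(self.structures),
                      "n_ligands": cfg.n_ligands})

    def stage_pockets(self) -> None:
        cfg = self.config
        rows = []
        all_pockets = []
        for s in self.structures:
            ps = detect_pockets(s)
            self.pockets_by_structure[s.label] = ps
            all_pockets.extend(ps)
            rows.append({"structure": s.label, "n_pockets": len(ps),
                         "largest_volume": ps[0].volume if ps else 0.0,
                         "largest_n_lining": ps[0].n_lining if ps else 0})
        bg = background_pocket_scores(all_pockets, cfg.pocket_background_pairs,
                                      seed=self.seeds["pockets"])
        self.pocket_calibrator = calibrate_pocket_pvalue(bg)
        pdir = self.outdir
        summary = pdir / "pockets_summary.tsv"
        _write_tsv(pd.DataFrame(rows), summary)
        bg_p = pdir / "pocket_background_scores.tsv"
        _write_tsv(pd.DataFrame({"score": bg}), bg_p)
        logger.info("pockets: %d total over %d structures",
                    len(all_pockets), len(self.structures))
        self._record("pockets", [summary, bg_p],
                     {"n_pockets": len(all_pockets),
                      "n_background": int(bg.size)})

    def stage_sites(self) -> None:
        cfg = self.config
        self.site_library = make_site_template_library(
            cfg.n_site_templates, seed=self.seeds["sites"])
        lib_p = self.outdir / "site_templates.json"
        save_template_library(self.site_library, lib_p)
        hits_rows = []
        hits_per_target = {c: {} for c in cfg.site_cutoffs}
        for s in self.structures:
            pockets = self.pockets_by_structure.get(s.label, [])
            region = (pockets[0].lining_indices if pockets
                      else range(s.n_residues))
            per_cut = scan_target(s, self.site_library,
                                  cutoffs=cfg.site_cutoffs,
                                  fold_filter_tm=cfg.fold_filter_tm,
                                  search_region=region)
            for cut, hits in per_cut.items():
                hits_per_target[cut][s.label] = hits
                for h in hits:
                    hits_rows.append({
                        "structure": s.label, "cutoff": cut,
                        "template": h.template_id, "ec": h.ec_number,
                        "rmsd": round(h.rmsd, 4),
                        "indices": ",".join(map(str, h.target_indices))})
        curve_rows = []
        for cut in cfg.site_cutoffs:
            _, curve = count_enzyme_classes(hits_per_target[cut], ec_digits=2)
            for k, frac in sorted(curve.items()):
                curve_rows.append({"cutoff": cut, "k": k,
                                   "cumulative_fraction": frac})
        hits_p = self.outdir / "site_hits.tsv"
        curves_p = self.outdir / "site_class_curves.tsv"
        _write_tsv(pd.DataFrame(hits_rows, columns=[
            "structure", "cutoff", "template", "ec", "rmsd", "indices"]), hits_p)
        _write_tsv(pd.DataFrame(curve_rows, columns=[
            "cutoff", "k", "cumulative_fraction"]), curves_p)
        n_hits = sum(1 for r in hits_rows if r["cutoff"] == max(cfg.site_cutoffs))
        logger.info("sites: %d hits at %.2f A over %d targets",
                    n_hits, max(cfg.site_cutoffs), len(self.structures))
        self._record("sites", [lib_p, hits_p, curves_p],
                     {"n_templates": len(self.site_library), "n_hits": n_hits})

    def stage_screen(self) -> None:
        cfg = self.config
        assert self.universe is not None and self.pocket_calibrator is not None
        rng = np.random.Generator(np.random.PCG64(self.seeds["screen"]))
        lig_ids = sorted(self.universe.fingerprints)
        fps = {k: v for k, v in self.universe.fingerprints.items()}
        path_ids = sorted(self.universe.pathways)
        # template pockets with known binders: the largest pockets of the
        # first few structures, each associated with one pathway's ligands
        donors = [s for s in self.structures
                  if self.pockets_by_structure.get(s.label)][:cfg.n_template_pockets]
        template_pockets = []
        for k, s in enumerate(donors):
            pathway = path_ids[k % len(path_ids)]
            ligs = self.universe.pathways[pathway]
            if not ligs:
                continue
            template_pockets.append(
                (self.pockets_by_structure[s.label][0], pathway,
                 [fps[l] for l in ligs]))
        targets = [s for s in self.structures
                   if self.pockets_by_structure.get(s.label)
                   and s.label not in {d.label for d in donors}]
        score_rows = []
        scores_by_protein: dict[str, np.ndarray] = {}
        for s in targets:
            own = self.pockets_by_structure[s.label][0]
            evidence = []
            for tp, pathway, tpl_fps in template_pockets:
                match = compare_pockets(own, tp)
                p = float(self.pocket_calibrator.pvalue(match.ps_like_score))
                evidence.append(PocketMatchEvidence(p, tpl_fps))
            svec = np.array([score_ligand(evidence, fps[l]) for l in lig_ids],
                            dtype=float)
            scores_by_protein[s.label] = svec
        all_scores = np.concatenate(list(scores_by_protein.values())) \
            if scores_by_protein else np.zeros(0)
        cut = call_threshold(all_scores, cfg.top_frac) if all_scores.size else 1.0
        predictions: dict[str, set[str]] = {}
        for label, svec in scores_by_protein.items():
            called = {lig_ids[i] for i in np.flatnonzero(svec > cut)}
            predictions[label] = called
            for i in np.flatnonzero(svec > cut):
                score_rows.append({"protein": label, "ligand": lig_ids[i],
                                   "score": round(float(svec[i]), 6), "call": 1})
        n_prot = len(predictions)
        n_calls = sum(len(v) for v in predictions.values())
        call_rate = (n_calls / (n_prot * len(lig_ids))) if n_prot else 0.0
        enrich_rows = []
        for pid in path_ids:
            ligs = self.universe.pathways[pid]
            if not ligs or call_rate == 0:
                enrich_rows.append({"pathway": pid, "enrichment_factor": np.nan,
                                    "n_ligands": len(ligs), "n_proteins": n_prot})
                continue
            pe = pathway_enrichment(predictions, ligs, pid, n_prot, call_rate)
            enrich_rows.append({"pathway": pid, "enrichment_factor": round(pe.e_p, 4),
                                "n_ligands": pe.n_ligands, "n_proteins": n_prot})
        med_l, frac, med_p = binding_statistics(predictions, lig_ids)
        pred_p = self.outdir / "screen_predictions.tsv"
        enrich_p = self.outdir / "pathway_enrichment.tsv"
        stats_p = self.outdir / "screen_statistics.json"
        _write_tsv(pd.DataFrame(score_rows, columns=[
            "protein", "ligand", "score", "call"]), pred_p)
        _write_tsv(pd.DataFrame(enrich_rows, columns=[
            "pathway", "enrichment_factor", "n_ligands", "n_proteins"]), enrich_p)
        stats_p.write_text(json.dumps({
            "median_targets_per_molecule": med_l,
            "fraction_molecules_with_target": frac,
            "median_molecules_per_protein": med_p,
            "call_rate": call_rate, "call_threshold": cut}, indent=1))
        logger.info("screen: %d proteins, call rate %.4f", n_prot, call_rate)
        self._record("screen", [pred_p, enrich_p, stats_p],
                     {"n_proteins": n_prot, "n_calls": n_calls})

    def stage_complexes(self) -> None:
        cfg = self.config
        rng = np.random.Generator(np.random.PCG64(self.seeds["complexes"]))
        templates = []
        for k in range(cfg.n_complex_templates):
            sa = int(rng.integers(2 ** 31))
            sb = int(rng.integers(2 ** 31))
            templates.append(make_dimer_template(sa, sb, min_contacts=10,
                                                 n_residues=cfg.min_residues))
        prop_table = cx.estimate_propensity_table(templates)
        monomers = self.structures
        bg = cx.shuffled_pair_background(monomers, templates, cfg.is_background,
                                         seed=int(rng.integers(2 ** 31)))
        calibrator = TailCalibrator(bg)
        rows = []
        accepted = []
        n_rejected = 0
        for _ in range(cfg.n_monomer_pairs):
            i, j = rng.choice(len(monomers), size=2, replace=False)
            t_idx = int(rng.integers(len(templates)))
            res = cx.assemble(monomers[int(i)], monomers[int(j)],
                              templates[t_idx], min_tm=cfg.complex_min_tm,
                              min_coverage=cfg.complex_min_coverage)
            if isinstance(res, cx.Rejection):
                n_rejected += 1
                rows.append({"template": t_idx, "monA": monomers[int(i)].label,
                             "monB": monomers[int(j)].label, "accepted": 0,
                             "coverageA": round(res.coverageA, 3),
                             "coverageB": round(res.coverageB, 3),
                             "e_pp": np.nan, "is_score": np.nan,
                             "is_p": np.nan, "class": "rejected"})
                continue
            cx.interaction_energy(res)
            cx.interface_similarity(res, calibrator=calibrator)
            accepted.append(res)
            rows.append({"template": t_idx, "monA": monomers[int(i)].label,
                         "monB": monomers[int(j)].label, "accepted": 1,
                         "coverageA": round(res.coverageA, 3),
                         "coverageB": round(res.coverageB, 3),
                         "e_pp": round(res.e_pp, 3),
                         "is_score": round(res.is_score, 4),
                         "is_p": res.is_p_value, "class": ""})
        attractive, repulsive, (hist, xe, ye) = cx.classify_and_density(
            accepted, e_cut=cfg.e_pp_attractive, p_cut=cfg.is_p_cut,
            e_repulsive=cfg.e_pp_repulsive)
        att_labels = {id(c) for c in attractive}
        rep_labels = {id(c) for c in repulsive}
        k = 0
        for r in rows:
            if r["accepted"]:
                c = accepted[k]
                r["class"] = ("attractive" if id(c) in att_labels else
                              "repulsive" if id(c) in rep_labels else "neutral")
                k += 1
        scores_p = self.outdir / "complex_scores.tsv"
        hist_p = self.outdir / "complex_density.tsv"
        prop_p = self.outdir / "pp_propensity_table.json"
        _write_tsv(pd.DataFrame(rows), scores_p)
        _write_tsv(_hist_frame(hist, xe, ye, "e_pp", "log10_is_p"), hist_p)
        prop_p.write_text(json.dumps(prop_table, indent=1, sort_keys=True))
        logger.info("complexes: %d accepted / %d rejected, %d attractive",
                    len(accepted), n_rejected, len(attractive))
        self._record("complexes", [scores_p, hist_p, prop_p],
                     {"n_accepted": len(accepted), "n_rejected": n_rejected,
                      "n_attractive": len(attractive)})

    def stage_dna(self) -> None:
        cfg = self.config
        rng = np.random.Generator(np.random.PCG64(self.seeds["dna"]))
        from foldfunc.generate import designed_monomer
        templates = []
        for _ in range(cfg.n_dna_templates):
            prot = designed_monomer(int(rng.integers(2 ** 31)),
                                    cfg.min_residues, mc_steps=cfg.mc_steps)
            templates.append(make_bdna_complex_template(
                cfg.n_bp, prot, seed=int(rng.integers(2 ** 31))))
        prop_table = dn.estimate_dna_propensity_table(templates)
        rows = []
        accepted = []
        n_rejected = 0
        for s in self.structures:
            t_idx = int(rng.integers(len(templates)))
            res = dn.assemble_dna(s, templates[t_idx], min_tm=cfg.dna_min_tm)
            if isinstance(res, dn.DnaRejection):
                n_rejected += 1
                continue
            dn.dna_interaction_energy(res)
            dn.interfacial_tm(res)
            accepted.append(res)
        attractive, repulsive, propensities, (hist, xe, ye) = \
            dn.dna_propensity_and_classify(accepted, prop_table,
                                           e_cut=cfg.e_dp_attractive,
                                           itm_cut=cfg.itm_cut,
                                           e_repulsive=cfg.e_dp_repulsive)
        att = {id(c) for c in attractive}
        rep = {id(c) for c in repulsive}
        for c, prop in zip(accepted, propensities):
            rows.append({"protein": c.label,
                         "e_dp": round(c.e_dp, 3),
                         "itm": round(c.itm_score, 4),
                         "propensity": round(prop.value, 4),
                         "class": ("attractive" if id(c) in att else
                                   "repulsive" if id(c) in rep else "neutral")})
        scores_p = self.outdir / "dna_scores.tsv"
        hist_p = self.outdir / "dna_density.tsv"
        prop_p = self.outdir / "dna_propensity_table.json"
        _write_tsv(pd.DataFrame(rows, columns=[
            "protein", "e_dp", "itm", "propensity", "class"]), scores_p)
        _write_tsv(_hist_frame(hist, xe, ye, "e_dp", "itm"), hist_p)
        prop_p.write_text(json.dumps(prop_table, indent=1, sort_keys=True))
        logger.info("dna: %d assembled, %d attractive", len(accepted),
                    len(attractive))
        self._record("dna", [scores_p, hist_p, prop_p],
                     {"n_assembled": len(accepted),
                      "n_attractive": len(attractive)})

    def stage_report(self) -> None:
        rep = generate_report(self.manifest, self.outdir)
        self._record("report", rep, {"n_files": len(rep)})


def _hist_frame(hist: np.ndarray, xe: np.ndarray, ye: np.ndarray,
                xname: str, yname: str) -> pd.DataFrame:
    rows = []
    for i in range(hist.shape[0] if hist.size else 0):
        for j in range(hist.shape[1]):
            rows.append({f"{xname}_lo": xe[i], f"{xname}_hi": xe[i + 1],
                         f"{yname}_lo": ye[j], f"{yname}_hi": ye[j + 1],
                         "count": int(hist[i, j])})
    cols = [f"{xname}_lo", f"{xname}_hi", f"{yname}_lo", f"{yname}_hi", "count"]
    return pd.DataFrame(rows, columns=cols)


def run_pipeline(config: ExperimentConfig) -> dict:
    """Run the configured stages in dependency order; returns the manifest.

    A stage failure is recorded in the manifest and its dependents are
    skipped.  Identical configurations produce identical output hashes.
    """
    run = PipelineRun(config)
    run.outdir.mkdir(parents=True, exist_ok=True)
    stage_fns = {
        "generate": run.stage_generate,
        "pockets": run.stage_pockets,
        "sites": run.stage_sites,
        "screen": run.stage_screen,
        "complexes": run.stage_complexes,
        "dna": run.stage_dna,
        "report": run.stage_report,
    }
    deps = {
        "generate": (),
        "pockets": ("generate",),
        "sites": ("generate", "pockets"),
        "screen": ("generate", "pockets"),
        "complexes": ("generate",),
        "dna": ("generate",),
        "report": (),
    }
    done: set[str] = set()
    failed: set[str] = set()
    for name in STAGES:
        if name not in config.stages:
            continue
        missing = [d for d in deps[name]
                   if d in config.stages and d not in done]
        blocked = [d for d in deps[name] if d in failed]
        if blocked or any(d not in done for d in deps[name] if d in config.stages):
            run.manifest["stages"][name] = {"skipped": True,
                                            "blocked_by": blocked or missing}
            continue
        try:
            stage_fns[name]()
            done.add(name)
        except Exception as exc:   # recorded, dependents skipped
            logger.exception("stage %s failed", name)
            failed.add(name)
            run.manifest["stages"][name] = {"failed": True, "error": str(exc)}
    manifest_p = run.outdir / "manifest.json"
    manifest_p.write_text(json.dumps(run.manifest, indent=1, sort_keys=True))
    return run.manifest


def generate_report(manifest: dict, outdir: pathlib.Path) -> list[pathlib.Path]:
    """Aggregate stage outputs into the report files.

    Raises with the stage name when an expected artifact is missing.
    """
    outdir = pathlib.Path(outdir)
    rdir = outdir / "report"
    rdir.mkdir(parents=True, exist_ok=True)
    written: list[pathlib.Path] = []
    summary: dict = {"counts": {}}
    for stage, info in manifest.get("stages", {}).items():
        if isinstance(info, dict) and "counts" in info:
            summary["counts"][stage] = info["counts"]
            for rel in info.get("outputs", {}):
                if not (outdir / rel).exists():
                    raise FileNotFoundError(
                        f"stage {stage}: missing artifact {rel}")
    # Table-1-style pathway report
    enrich = outdir / "pathway_enrichment.tsv"
    if enrich.exists():
        df = pd.read_csv(enrich, sep="\t")
        df = df.sort_values("enrichment_factor", ascending=False)
        top = rdir / "top_pathways.tsv"
        _write_tsv(df, top)
        written.append(top)
    curves = outdir / "site_class_curves.tsv"
    if curves.exists():
        dst = rdir / "site_class_curves.tsv"
        dst.write_text(curves.read_text())
        written.append(dst)
    sp = rdir / "summary.json"
    sp.write_text(json.dumps(summary, indent=1, sort_keys=True))
    written.append(sp)
    return written
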