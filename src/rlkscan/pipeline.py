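"""Config-driven orchestration of the full analysis workflow.

Stage order mirrors the candidate-isolation study design: amplify (in-silico
PCR) → screen (ORF) → annotate (kinase motifs) → phylogeny (Poisson + NJ +
bootstrap + subfamily assignment) → selection (sliding-window Ka/Ks) →
variability (non-synonymous position map).  Every stage writes plain-text
artifacts into the run directory plus a JSON manifest with the seed, a
config hash and per-stage counts; the same config and seed reproduce all
artifacts byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .align import CodonAlignment, backtranslate_alignment, translate_nt
from .motifs import (KinaseAnnotation, annotate, summarize_families,
                     write_annotation_tsv)
from .pcr import DegeneratePrimer, insilico_pcr, orf_screen, read_primer_tsv, \
    write_amplicon_tsv
from .phylo import assign_groups, bootstrap_support, poisson_distance, \
    read_reference_panel, write_distance_tsv
from .records import SeqRecord, read_fasta, write_fasta
from .selection import compare_two_windows, compare_window_groups, \
    test_window_vs_one, window_profile, write_comparison_tsv, write_profile_tsv
from .simulate import SimConfig, plant_primer_sites, simulate_family
from .variability import nonsyn_position_map, shared_position_summary, \
    write_variability_tsv

logger = logging.getLogger(__name__)

# default degenerate primer pair used to flank simulated templates
DEFAULT_FWD = DegeneratePrimer("simF", "GGNACNGARTTYGCNAC", "forward")
DEFAULT_REV = DegeneratePrimer("simR", "TCNGGRTARTCNCCYTG", "reverse")

ALL_STAGES = ("amplify", "screen", "annotate", "phylogeny", "selection", "variability")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs, parameters and stage toggles for one run.

    Either ``simulate`` or (``codon_alignment_path`` + ``groups_path``)
    must be set.
    """

    out_dir: str = "rlkscan_run"
    simulate: SimConfig | None = None
    codon_alignment_path: str | None = None
    groups_path: str | None = None
    primers_path: str | None = None
    reference_panel_path: str | None = None
    stages: tuple[str, ...] = ALL_STAGES
    window_nt: int = 75
    step_nt: int = 15
    alpha: float = 1e-4
    fold_min: float = 2.0
    bootstrap_replicates: int = 100
    min_support: float = 70.0
    method: str = "NG86"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulate is None and not (self.codon_alignment_path and self.groups_path):
            raise ValueError("config needs a simulate block or input paths")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not (0 < self.alpha < 1) or self.fold_min <= 0 or self.bootstrap_replicates < 1:
            raise ValueError("parameter out of documented range")


def _config_hash(cfg: PipelineConfig) -> str:
    # the output directory is not part of the scientific configuration
    fields = {k: v for k, v in dataclasses.asdict(cfg).items() if k != "out_dir"}
    blob = json.dumps(fields, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def read_groups_tsv(path) -> dict[str, list[str]]:
    """Group membership TSV: seq_id, group (``#`` comments allowed)."""
    groups: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            seq_id, group = ln.split("\t")[:2]
            groups.setdefault(group, []).append(seq_id)
    return groups


def write_groups_tsv(groups: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("# seq_id\tgroup\n")
        for g, members in groups.items():
            for m in members:
                fh.write(f"{m}\t{g}\n")


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the configured stages in order; returns the run directory.

    Any stage error halts the pipeline with the stage name; artifacts of
    completed stages are preserved.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "stages": {},
    }
    rng = np.random.default_rng(cfg.seed)

    # ------------------------------------------------------------------ inputs
    pseudogenes: dict[str, str] = {}
    if cfg.simulate is not None:
        sim = simulate_family(dataclasses.replace(cfg.simulate, seed=cfg.seed))
        aln = sim.alignment
        groups = sim.groups
        pseudogenes = sim.pseudogenes
        write_fasta(aln.records, out / "alignment.fasta")
        write_groups_tsv(groups, out / "groups.tsv")
        with open(out / "truth_events.tsv", "w") as fh:
            fh.write("# lineage\tcodon_pos\tfrom\tto\tsynonymous\n")
            for e in sim.events:
                fh.write(
                    f"{e.lineage}\t{e.codon_pos}\t{e.from_codon}\t{e.to_codon}"
                    f"\t{int(e.synonymous)}\n"
                )
        manifest["stages"]["simulate"] = {
            "n_sequences": len(aln.records),
            "n_groups": len(groups),
            "n_codons": aln.n_codons,
            "n_events": len(sim.events),
            "n_pseudogenes": len(pseudogenes),
        }
    else:
        recs = read_fasta(cfg.codon_alignment_path, alphabet="nt", aligned=True)
        aln = CodonAlignment(tuple(recs))
        groups = read_groups_tsv(cfg.groups_path)

    templates = {r.id: r.ungapped for r in aln.records}
    templates.update(pseudogenes)

    # ------------------------------------------------------------------ amplify
    if "amplify" in cfg.stages:
        try:
            if cfg.primers_path:
                primers = read_primer_tsv(cfg.primers_path)
                fwd = next(p for p in primers if p.direction == "forward")
                rev = next(p for p in primers if p.direction == "reverse")
            else:
                fwd, rev = DEFAULT_FWD, DEFAULT_REV
            amplified: dict[str, str] = {}
            all_amps = []
            for tid, seq in sorted(templates.items()):
                flanked = plant_primer_sites(
                    "N" * len(fwd.iupac) + seq + "N" * len(rev.iupac),
                    fwd, rev,
                    positions=(0, len(fwd.iupac) + len(seq)),
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                template = SeqRecord(id=tid, residues=flanked, alphabet="nt")
                amps = insilico_pcr(template, fwd, rev, max_mismatches=0)
                all_amps.extend(amps)
                if amps:
                    # primer-trimmed product (default behaviour)
                    amplified[tid] = amps[0].trimmed(len(fwd.iupac), len(rev.iupac))
            write_amplicon_tsv(all_amps, out / "amplicons.tsv")
            manifest["stages"]["amplify"] = {
                "n_templates": len(templates), "n_amplicons": len(all_amps),
            }
            templates = amplified
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("amplify", str(exc)) from exc

    # ------------------------------------------------------------------ screen
    intact_ids: list[str] = []
    if "screen" in cfg.stages:
        try:
            with open(out / "orf_report.tsv", "w") as fh:
                fh.write("# seq_id\tstatus\tn_internal_stops\tstop_codon_indices\n")
                for tid, seq in sorted(templates.items()):
                    res = orf_screen(seq, frame_offset=0)
                    fh.write(
                        f"{tid}\t{res.status}\t{len(res.reasons)}\t"
                        f"{','.join(map(str, res.reasons)) or '-'}\n"
                    )
                    if res.status == "intact":
                        intact_ids.append(tid)
            n_total = len(templates)
            manifest["stages"]["screen"] = {
                "n_screened": n_total,
                "n_intact": len(intact_ids),
                "n_interrupted": n_total - len(intact_ids),
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("screen", str(exc)) from exc
    else:
        intact_ids = sorted(templates)

    analysis_ids = [i for i in aln.ids if i in intact_ids]
    analysis_groups = {
        g: [m for m in members if m in analysis_ids] for g, members in groups.items()
    }
    analysis_groups = {g: m for g, m in analysis_groups.items() if len(m) >= 2}

    # ------------------------------------------------------------------ annotate
    annotations: list[KinaseAnnotation] = []
    if "annotate" in cfg.stages:
        try:
            aa_seqs = {
                i: SeqRecord(id=i, residues=translate_nt(aln[i].ungapped), alphabet="aa")
                for i in analysis_ids
            }
            for i in analysis_ids:
                annotations.append(annotate(aa_seqs[i]))
            write_annotation_tsv(annotations, out / "annotations.tsv")
            assignments = {
                m: g for g, members in analysis_groups.items() for m in members
            }
            nt_seqs = {i: SeqRecord(id=i, residues=aln[i].ungapped, alphabet="nt")
                       for i in analysis_ids}
            summary = summarize_families(annotations, assignments, nt_seqs)
            summary.to_csv(out / "family_summary.tsv", sep="\t", index=False)
            manifest["stages"]["annotate"] = {
                "n_annotated": len(annotations),
                "n_nonRD": sum(a.catalytic_class == "nonRD" for a in annotations),
                "n_RD": sum(a.catalytic_class == "RD" for a in annotations),
                "n_atypical": sum(a.kinase_class == "atypical" for a in annotations),
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("annotate", str(exc)) from exc

    # ------------------------------------------------------------------ phylogeny
    if "phylogeny" in cfg.stages:
        try:
            prot = CodonAlignment(
                tuple(aln[i] for i in analysis_ids)
            ).to_protein() if len(analysis_ids) >= 2 else None
            if prot is None or len(analysis_ids) < 3:
                raise ValueError("phylogeny needs at least 3 intact sequences")
            dm = poisson_distance(prot)
            write_distance_tsv(dm, out / "distances.tsv")
            tree = bootstrap_support(
                prot, replicates=cfg.bootstrap_replicates, seed=cfg.seed
            )
            (out / "tree.nwk").write_text(tree.to_newick() + "\n")
            if cfg.reference_panel_path:
                refs = read_reference_panel(cfg.reference_panel_path)
            else:
                # first member of each group serves as its reference
                refs = {m[0]: g for g, m in analysis_groups.items() if m}
            missing = [r for r in refs if r not in tree.leaf_names()]
            if missing and cfg.reference_panel_path:
                raise ValueError(f"reference leaves absent from tree: {missing}")
            ga = assign_groups(tree, refs, min_support=cfg.min_support)
            with open(out / "assignments.tsv", "w") as fh:
                fh.write("# seq_id\tsubfamily\tsupport\tnearest_references\n")
                for q in sorted(ga.labels):
                    sup = ga.support[q]
                    fh.write(
                        f"{q}\t{ga.labels[q]}\t{'' if sup is None else f'{sup:g}'}\t"
                        f"{','.join(ga.nearest_references[q]) or '-'}\n"
                    )
            n_uncertain = sum(1 for v in ga.labels.values() if v == "uncertain")
            manifest["stages"]["phylogeny"] = {
                "n_leaves": len(tree.leaf_names()),
                "n_queries": len(ga.labels),
                "n_assigned": len(ga.labels) - n_uncertain,
                "n_uncertain": n_uncertain,
                "bootstrap_replicates": cfg.bootstrap_replicates,
            }
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("phylogeny", str(exc)) from exc

    # ------------------------------------------------------------------ selection
    if "selection" in cfg.stages:
        try:
            profiles = {}
            for g, members in analysis_groups.items():
                profiles[g] = window_profile(
                    aln, members, group_label=g, window_nt=cfg.window_nt,
                    step_nt=cfg.step_nt, method=cfg.method,
                )
            all_profiles = [p for ps in profiles.values() for p in ps]
            write_profile_tsv(all_profiles, out / "window_profiles.tsv")
            comparisons = []
            labels = sorted(profiles)
            control = labels[-1]
            for g in labels[:-1]:
                comparisons.extend(
                    compare_window_groups(
                        profiles[g], profiles[control],
                        alpha=cfg.alpha, fold_min=cfg.fold_min,
                    )
                )
            # within-group contrast: highest-mean vs lowest-mean window
            for g, ps in profiles.items():
                defined = [p for p in ps if p.n_pairs_used >= 2]
                if len(defined) >= 2:
                    hi = max(defined, key=lambda p: p.mean)
                    lo = min(defined, key=lambda p: p.mean)
                    if hi.window_index != lo.window_index:
                        comparisons.append(
                            compare_two_windows(ps, hi.window_index, lo.window_index,
                                                alpha=cfg.alpha, fold_min=cfg.fold_min)
                        )
            write_comparison_tsv(comparisons, out / "window_comparisons.tsv")
            with open(out / "window_vs_one.tsv", "w") as fh:
                fh.write("# group\twindow_index\tp_value\texceeds_one\n")
                for g, ps in profiles.items():
                    for p in ps:
                        if len(p.omegas) >= 2:
                            pv, exceeds = test_window_vs_one(p)
                            fh.write(f"{g}\t{p.window_index}\t{pv:.4g}\t{int(exceeds)}\n")
            manifest["stages"]["selection"] = {
                "n_groups": len(profiles),
                "n_windows": len(next(iter(profiles.values()))) if profiles else 0,
                "n_comparisons": len(comparisons),
                "n_significant": sum(c.flag_significant for c in comparisons),
                "method": cfg.method,
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("selection", str(exc)) from exc

    # ------------------------------------------------------------------ variability
    if "variability" in cfg.stages:
        try:
            vt = nonsyn_position_map(aln, analysis_groups)
            write_variability_tsv(vt, out / "variability.tsv")
            summary = shared_position_summary(vt)
            manifest["stages"]["variability"] = summary
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("variability", str(exc)) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %s", out)
    return out
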