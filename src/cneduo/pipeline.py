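"""End-to-end orchestration: simulate -> discover -> orient -> complementarity
-> retention -> state -> correlate, from one YAML config, with a
machine-readable report and ledger-vs-result recovery scores.

All randomness flows from one root seed; a seeded run is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import coexpression, discovery, io_formats, regulatory_state, retention, synthetic
from .complementarity import OrientedPair, detect_compensatory_events, infer_orientation, revcomp
from .io_formats import GenomicInterval
from .regulatory_state import StateThresholds
from .synthetic import SimulationConfig

log = logging.getLogger("cneduo.pipeline")

STAGES = ("simulate", "discover", "complementarity", "retention", "state", "correlate")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunReport:
    config: dict
    stages: dict[str, dict] = field(default_factory=dict)
    recovery: dict[str, float] = field(default_factory=dict)
    output_paths: dict[str, str] = field(default_factory=dict)
    warnings: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunReport":
        data = json.loads(Path(path).read_text())
        return cls(**data)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    for key in cfg:
        if key not in ("seed", "out_dir", "simulate", "discover", "state", "correlate", "thresholds"):
            raise ValueError(f"unknown config section {key!r}")
    return cfg


def _sim_config(cfg: Mapping[str, Any]) -> SimulationConfig:
    sim = dict(cfg.get("simulate") or {})
    for key in ("drop_c_in", "no_assembly", "omit_host_transcript_in"):
        if key in sim:
            sim[key] = tuple(sim[key])
    if "nc_coding_pair" in sim:
        sim["nc_coding_pair"] = tuple(sim["nc_coding_pair"])
    return SimulationConfig(seed=int(cfg.get("seed", 0)), **sim)


def run_pipeline(
    config: str | Path | Mapping[str, Any],
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> RunReport:
    """Run every stage in dependency order and score results against the ledger."""
    t0 = time.time()
    cfg = dict(load_config(config)) if isinstance(config, (str, Path)) else dict(config)
    if seed is not None:
        cfg["seed"] = seed
    out = Path(out_dir or cfg.get("out_dir", "cneduo_run"))
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=json.loads(json.dumps(cfg, default=str)))

    # ---- simulate -------------------------------------------------------
    try:
        sim_cfg = _sim_config(cfg)
        ancestor = synthetic.simulate_ancestral_cluster(sim_cfg)
        clade = synthetic.simulate_wgd_and_divergence(ancestor, sim_cfg)
        host = next(
            t for t in clade.annotations[next(iter(clade.genomes))]
            if t.gene_id.startswith("hostC")
        )
        libraries = synthetic.simulate_intron_retained_reads(host, sim_cfg)
        states = list((cfg.get("state") or {}).get("states", ["closed", "poised", "active"]))
        first_sp = next(iter(clade.genomes))
        element = clade.ledger.cne_intervals[(first_sp, "C")]
        scenarios = {
            st: synthetic.simulate_cage_and_signals(element, st, sim_cfg) for st in states
        }
        matrix, expr_ledger = synthetic.simulate_expression_matrix(sim_cfg)

        genome_dir = out / "genomes"
        genome_dir.mkdir(exist_ok=True)
        for sp, genome in clade.genomes.items():
            io_formats.write_fasta(genome, genome_dir / f"{sp}.fa")
            io_formats.write_gff3(clade.annotations[sp], genome_dir / f"{sp}.gff3")
        for lib, reads in libraries.items():
            io_formats.write_bed12(reads, out / f"reads_{lib}.bed12")
        for st, sc in scenarios.items():
            io_formats.write_ctss_bed(sc.ctss, out / f"ctss_{st}.bed")
            for mark, track in sc.tracks.items():
                io_formats.write_bedgraph(track, out / f"{st}_{mark}.bedgraph")
        io_formats.write_expression_tsv(matrix, out / "expression.tsv")
        clade.ledger.retention_fraction = sim_cfg.retention_fraction
        clade.ledger.to_tsv(out / "truth_ledger.tsv")
        report.stages["simulate"] = {
            "species": sorted(clade.genomes),
            "n_compensatory_events": len(clade.ledger.events),
            "states": states,
            "n_samples": sim_cfg.n_samples,
        }
        report.output_paths["genomes"] = str(genome_dir)
        report.output_paths["expression"] = str(out / "expression.tsv")
        report.output_paths["truth_ledger"] = str(out / "truth_ledger.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulate", str(exc)) from exc

    # ---- discover -------------------------------------------------------
    try:
        disc_cfg = cfg.get("discover") or {}
        min_identity = float(disc_cfg.get("min_identity", 0.75))
        seed_len = int(disc_cfg.get("seed_len", 8))
        log.info("discover: min_identity=%s seed_len=%s", min_identity, seed_len)
        query = ancestor.cne_seq
        hits_by_species: dict[str, list[discovery.CneHit]] = {}
        for sp, genome in clade.genomes.items():
            hits = discovery.scan_homologs(query, genome, min_identity, seed_len, species=sp)
            hits_by_species[sp] = [
                discovery.assign_synteny(h, clade.annotations[sp]) for h in hits
            ]
        species = sorted(set(clade.genomes) | set(clade.ledger.no_assembly))
        matrix_pa = discovery.build_presence_matrix(
            hits_by_species, species, no_assembly=clade.ledger.no_assembly
        )
        matrix_pa.to_csv(out / "presence_matrix.tsv", sep="\t", index_label="species")
        planted = [
            (sp, cl) for (sp, cl) in clade.ledger.cne_intervals if sp in clade.genomes
        ]
        recovered = 0
        for sp, cl in planted:
            iv = clade.ledger.cne_intervals[(sp, cl)]
            for h in hits_by_species.get(sp, ()):
                if h.cluster == cl and h.interval.seq_id == iv.seq_id and \
                        h.interval.start == iv.start and h.interval.end == iv.end:
                    recovered += 1
                    break
        report.recovery["discovery_recovery"] = recovered / len(planted) if planted else 1.0
        report.stages["discover"] = {
            "n_hits": sum(len(v) for v in hits_by_species.values()),
            "n_planted": len(planted),
            "min_identity": min_identity,
            "seed_len": seed_len,
        }
        report.output_paths["presence_matrix"] = str(out / "presence_matrix.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("discover", str(exc)) from exc

    # ---- complementarity ------------------------------------------------
    try:
        pairs: dict[str, OrientedPair] = {}
        orientation_correct = 0
        orientation_total = 0
        for sp in clade.genomes:
            if (sp, "C") not in clade.ledger.cne_intervals:
                continue
            oriented: dict[str, str] = {}
            for cl in ("C", "D"):
                best = max(
                    (h for h in hits_by_species[sp] if h.cluster == cl),
                    key=lambda h: h.identity,
                    default=None,
                )
                if best is None:
                    break
                pattern = "c11" if cl == "C" else "d11"
                strand, _prov = infer_orientation(
                    best.interval, clade.annotations[sp], gene11_pattern=pattern
                )
                orientation_total += 1
                if strand == clade.ledger.host_orientation[(sp, cl)]:
                    orientation_correct += 1
                seq = clade.genomes[sp][best.interval.seq_id][
                    best.interval.start : best.interval.end
                ]
                oriented[cl] = seq if strand == "+" else revcomp(seq)
            if len(oriented) == 2:
                pairs[sp] = OrientedPair(sp, oriented["C"], oriented["D"])
        leaf_names = set(clade.genomes) - set(clade.ledger.dropped_c)
        comp_summary: dict[str, Any] = {"n_pairs": len(pairs)}
        if pairs and set(pairs) == leaf_names and not clade.ledger.dropped_c \
                and not clade.ledger.no_assembly:
            from .complementarity import complementarity_profile

            scores = {sp: complementarity_profile(p).score for sp, p in pairs.items()}
            result = detect_compensatory_events(pairs, clade.tree)
            truth = {
                (ev.branch, ev.c_column, ev.d_column, ev.event_class)
                for ev in clade.ledger.events
            }
            found = {
                (c.branch, c.c_column, c.d_column, c.call_class) for c in result.calls
            }
            tp = len(truth & found)
            precision = tp / len(found) if found else (1.0 if not truth else 0.0)
            recall = tp / len(truth) if truth else 1.0
            report.recovery["compensatory_precision"] = precision
            report.recovery["compensatory_recall"] = recall
            comp_summary.update(
                n_events=len(result.events),
                n_calls=len(result.calls),
                mean_complementarity=float(np.mean(list(scores.values()))),
            )
            calls_path = out / "compensatory_calls.tsv"
            with open(calls_path, "w") as fh:
                fh.write("branch\tc_column\td_column\tclass\n")
                for c in result.calls:
                    fh.write(f"{c.branch}\t{c.c_column}\t{c.d_column}\t{c.call_class}\n")
            report.output_paths["compensatory_calls"] = str(calls_path)
        if orientation_total:
            report.recovery["orientation_accuracy"] = orientation_correct / orientation_total
        report.stages["complementarity"] = comp_summary
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("complementarity", str(exc)) from exc

    # ---- retention ------------------------------------------------------
    try:
        counts = {
            lib: retention.count_library(reads, host, lib)
            for lib, reads in libraries.items()
        }
        summary = retention.summarize_retention(counts)
        true_r = sim_cfg.retention_fraction
        est = summary.intron_fraction.get("whole_cell")
        report.recovery["retention_abs_error"] = abs(est - true_r) if est is not None else float("nan")
        report.stages["retention"] = {
            "intron_fraction": summary.intron_fraction,
            "compartment_log2_ratio": summary.compartment_log2_ratio,
            "true_retention_fraction": true_r,
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("retention", str(exc)) from exc

    # ---- state ----------------------------------------------------------
    try:
        th = StateThresholds(**(cfg.get("thresholds") or {}))
        state_map = {"closed": "closed", "poised": "poised_enhancer", "active": "active_enhancer"}
        calls = {}
        correct = 0
        spacing_error = None
        uncovered = 0
        for st, sc in scenarios.items():
            clusters = regulatory_state.cluster_ctss(sc.ctss, th.max_gap)
            bp = regulatory_state.find_bidirectional_pairs(
                clusters, sc.element, th.window, th.spacing_band
            )
            ev = regulatory_state.signal_features(
                sc.tracks, sc.element, bimodal_ratio=th.bimodal_ratio
            )
            uncovered += int(ev.get("uncovered_positions", 0))
            call = regulatory_state.call_state(ev, bp, sc.element, cell_type=st, thresholds=th)
            calls[st] = call.state
            if call.state == state_map[st]:
                correct += 1
            if st == "active" and bp:
                spacing_error = abs(bp[0].spacing - sim_cfg.cage_spacing)
        report.recovery["state_accuracy"] = correct / len(scenarios)
        if spacing_error is not None:
            report.recovery["spacing_abs_error_bp"] = float(spacing_error)
        report.warnings["uncovered_track_positions"] = uncovered
        report.stages["state"] = {
            "calls": calls,
            # json round-trip keeps the report equal to its re-loaded form
            "thresholds": json.loads(json.dumps(dataclasses.asdict(th))),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("state", str(exc)) from exc

    # ---- correlate ------------------------------------------------------
    try:
        corr_cfg = cfg.get("correlate") or {}
        method = corr_cfg.get("method", "pearson-log")
        threshold = float(corr_cfg.get("threshold", 1.0))
        genes = list(corr_cfg.get("genes", sorted(expr_ledger.couplings))) or sorted(
            expr_ledger.couplings
        )
        table = coexpression.cis_trans_table(
            matrix, synthetic.ELEMENT_FEATURE, genes, threshold, method
        )
        table.to_csv(out / "correlations.tsv", sep="\t", index=False)
        sign_hits = 0
        sign_total = 0
        for _, row in table.iterrows():
            rho = expr_ledger.couplings.get(row["gene"])
            if rho is None or rho == 0 or not np.isfinite(row["r"]):
                continue
            sign_total += 1
            if np.sign(row["r"]) == np.sign(rho):
                sign_hits += 1
        if sign_total:
            report.recovery["correlation_sign_recovery"] = sign_hits / sign_total
        nc_id, coding_id, fold = sim_cfg.nc_coding_pair
        _ratios, ratio_summary = coexpression.promoter_ratio(matrix, nc_id, coding_id)
        report.recovery["promoter_ratio_abs_error"] = abs(
            ratio_summary["median_log2_ratio"] - np.log2(fold)
        )
        report.stages["correlate"] = {
            "method": method,
            "threshold": threshold,
            "table": table.to_dict(orient="records"),
            "promoter_ratio": ratio_summary,
        }
        report.output_paths["correlations"] = str(out / "correlations.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("correlate", str(exc)) from exc

    log.info("pipeline finished in %.1f s", time.time() - t0)
    report.output_paths["report"] = str(out / "report.json")
    report.to_json(out / "report.json")
    return report
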