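"""Per-animal and cohort orchestration: load or generate data, run every stage,
emit tables, reports, and a run manifest.

The pipeline composes the library's stages in the order an analyst would:
align sessions, build coactivity networks, compare training against testing
(and the two post-learning reactivation sessions against each other), profile
ensemble reactivation and location-gated activity, place NE-specific neurons
topologically, peel the training-edge networks, and — at cohort level —
assemble the six remodelling features and run the leave-one-out classifier.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classification import assemble_features, loocv_classify
from .comparison import compare_sessions
from .ensembles import NeuronSet, active_set, gate_raster, ne_specific, reactivation_fraction
from .networks import (
    build_network,
    coactivation_frequency,
    edge_presence,
    edge_set,
    location_edges,
    network_summary,
    restricted_strength,
)
from .rasters import (
    AnimalRecord,
    read_animal_records,
    read_event_table,
    read_occupancy,
    read_registration,
    write_animal_records,
    write_event_table,
    write_occupancy,
    write_registration,
)
from .synthetic import GeneratorParams, SessionBundle, simulate_animal, simulate_cohort
from .topology import centralities, compare_subgroups, kcore_peeling, training_edge_subgraph, zscore_table

log = logging.getLogger("engramnet")

__all__ = ["PipelineConfig", "run_animal", "run_cohort", "write_bundle", "read_bundle"]


@dataclasses.dataclass
class PipelineConfig:
    """Validated knobs for a pipeline run."""

    window_len: int = 10
    step: int = 1
    min_weight: int = 1
    lead_frames: int = 10
    min_events: int = 1
    l1_ratio: float = 0.5
    reg_strength: float = 1.0
    leakage_mode: str = "fold"
    seed: int = 0
    n_per_group: int = 7
    generator: GeneratorParams = dataclasses.field(default_factory=GeneratorParams)

    def __post_init__(self) -> None:
        if self.window_len < 1 or self.step < 1 or self.min_weight < 1 or self.min_events < 1:
            raise ValueError("window_len, step, min_weight and min_events must be >= 1")
        if self.lead_frames < 0:
            raise ValueError("lead_frames must be >= 0")
        if not 0.0 <= self.l1_ratio <= 1.0:
            raise ValueError("l1_ratio must lie in [0, 1]")
        if self.reg_strength <= 0:
            raise ValueError("reg_strength must be positive")
        if self.leakage_mode not in ("fold", "cohort"):
            raise ValueError("leakage_mode must be 'fold' or 'cohort'")
        if self.generator.n_frames < self.window_len:
            raise ValueError("session length must cover at least one window")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = GeneratorParams(**raw.pop("generator", {}))
        return cls(generator=gen, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _json_default(o):
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _dump(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)


def write_bundle(bundle: SessionBundle, outdir) -> None:
    """Serialise a synthetic animal to the package's own text formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sess, raster in bundle.rasters.items():
        write_event_table(raster, outdir / f"events_{sess}.csv")
    write_registration(bundle.regmap, outdir / "registration.csv")
    for sess, occ in bundle.occupancy.items():
        write_occupancy(occ, outdir / f"occupancy_{sess}.csv")
    write_animal_records([bundle.record], outdir / "animal.csv")
    bundle.ground_truth.write_json(outdir / "ground_truth.json")
    meta = {
        "animal_id": bundle.animal_id,
        "scenario": bundle.scenario,
        "sessions": sorted(bundle.rasters),
        "n_frames": {s: r.n_frames for s, r in bundle.rasters.items()},
        "frame_period": {s: r.frame_period for s, r in bundle.rasters.items()},
    }
    _dump(meta, outdir / "bundle.json")


def read_bundle(indir) -> dict:
    """Load the raster/registration/occupancy/record files written by write_bundle.

    Returns a dict with rasters, regmap, occupancy, and record (no ground truth
    is needed to analyse an animal).
    """
    indir = Path(indir)
    with open(indir / "bundle.json") as fh:
        meta = json.load(fh)
    regmap = read_registration(indir / "registration.csv")
    rasters = {}
    for sess in meta["sessions"]:
        # column order = session_index order recorded in the registration map
        ids = [g for g, _ in sorted(regmap.session_map(sess).items(), key=lambda t: t[1])]
        rasters[sess] = read_event_table(
            indir / f"events_{sess}.csv",
            frame_period=meta["frame_period"][sess],
            n_frames=meta["n_frames"][sess],
            neuron_ids=ids,
            session_id=sess,
        )
    occupancy = {}
    for sess in ("training", "test"):
        p = indir / f"occupancy_{sess}.csv"
        if p.exists():
            occupancy[sess] = read_occupancy(p, n_frames=meta["n_frames"][sess])
    record = read_animal_records(indir / "animal.csv")[0]
    return {"rasters": rasters, "regmap": regmap, "occupancy": occupancy, "record": record}


def run_animal(config: PipelineConfig, bundle: SessionBundle | dict, outdir) -> dict:
    """Run the full per-animal analysis and write its artifact set.

    Produces (when the needed sessions are present; missing sessions skip
    their dependent outputs with a logged warning):

    * training-vs-test and post_early-vs-post_late ComparisonReports;
    * ensemble reactivation of the training-active set in every later session;
    * location-A ensemble and edge statistics on the training session;
    * a centrality table (raw + z-scored) for the test network with the
      NE-specific subgroup comparison;
    * k-core peeling curves of the training-edge networks at post_early and
      post_late;
    * a run manifest (version, seed, parameters).
    """
    if isinstance(bundle, SessionBundle):
        data = {
            "rasters": bundle.rasters,
            "regmap": bundle.regmap,
            "occupancy": bundle.occupancy,
            "record": bundle.record,
        }
        animal_id = bundle.animal_id
    else:
        data = bundle
        animal_id = data["record"].animal_id
    rasters, regmap = data["rasters"], data["regmap"]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {"animal_id": animal_id}

    def have(*sessions):
        missing = [s for s in sessions if s not in rasters]
        if missing:
            log.warning("animal %s: missing sessions %s; skipping dependent outputs", animal_id, missing)
            return False
        return True

    kw = dict(window_len=config.window_len, step=config.step, min_weight=config.min_weight)
    if have("training", "test"):
        rep = compare_sessions(rasters["training"], rasters["test"], regmap, **kw)
        rep.write_json(outdir / "compare_training_test.json")
        results["training_vs_test"] = rep
    if have("post_early", "post_late"):
        rep_post = compare_sessions(rasters["post_early"], rasters["post_late"], regmap, **kw)
        rep_post.write_json(outdir / "compare_post_early_late.json")
        results["post_early_vs_late"] = rep_post

    if have("training"):
        net_tr = build_network(rasters["training"], config.window_len, config.step)
        e_tr = edge_set(net_tr, config.min_weight, label="training")
        ens_tr = active_set(rasters["training"], config.min_events, label="training ensemble")
        ens_tr.write_csv(outdir / "training_ensemble.csv")
        reactivation = {}
        for sess in ("post_early", "post_late", "NE", "test"):
            if sess in rasters:
                reactivation[sess] = reactivation_fraction(ens_tr, rasters[sess], config.min_events)
        _dump(reactivation, outdir / "ensemble_reactivation.json")
        results["reactivation"] = reactivation

        occ = data.get("occupancy", {}).get("training")
        if occ is not None and "locationA" in occ.labels():
            loc_edges = location_edges(
                rasters["training"], occ, "locationA", config.lead_frames,
                config.window_len, config.step, config.min_weight,
            )
            loc_edges.write_csv(outdir / "locationA_edges_training.csv")
            gated = gate_raster(rasters["training"], occ, "locationA", config.lead_frames)
            loc_ens = active_set(gated, config.min_events, label="locationA ensemble")
            loc_ens.write_csv(outdir / "locationA_ensemble.csv")
            loc_stats = {
                "n_locationA_edges": len(loc_edges),
                "n_training_edges": len(e_tr),
                "locationA_edge_fraction": (len(loc_edges) / len(e_tr)) if len(e_tr) else None,
                "n_locationA_neurons": len(loc_ens),
            }
            if "test" in rasters and len(loc_edges) > 0:
                net_te_full = build_network(rasters["test"], config.window_len, config.step)
                loc_stats["locationA_edge_presence_test"] = edge_presence(
                    loc_edges, net_te_full, config.min_weight
                )
            _dump(loc_stats, outdir / "locationA_stats.json")
            results["locationA"] = loc_stats

        if have("training", "test"):
            net_te = build_network(rasters["test"], config.window_len, config.step)
            summ = network_summary(net_te, config.min_weight)
            _dump(dataclasses.asdict(summ), outdir / "test_network_summary.json")
            rs = restricted_strength(net_te, e_tr)
            _dump({str(k): v for k, v in rs.items()}, outdir / "restricted_strength_test.json")
            results["test_summary"] = summ
            results["coactivation_frequency_test"] = coactivation_frequency(e_tr, net_te)

            table = zscore_table(centralities(net_te, config.min_weight))
            if "NE" in rasters:
                ne_set = ne_specific(rasters["NE"], rasters["training"], regmap)
                results["ne_set"] = ne_set
                if 0 < len(ne_set.ids & set(table.node_ids)) and len(ne_set.ids) < len(table.node_ids):
                    comp = compare_subgroups(table, ne_set)
                    comp.write_json(outdir / "ne_subgroup_comparison.json")
                    results["ne_comparison"] = comp
            table.write_csv(outdir / "test_centralities.csv")
            results["centralities"] = table

        peels = {}
        for sess in ("post_early", "post_late"):
            if sess in rasters:
                net_p = build_network(rasters[sess], config.window_len, config.step)
                peel = kcore_peeling(training_edge_subgraph(net_p, e_tr, config.min_weight))
                peel.write_csv(outdir / f"peeling_{sess}.csv")
                _dump(peel.summary(), outdir / f"peeling_{sess}.json")
                peels[sess] = peel
                results[f"presence_{sess}"] = edge_presence(
                    e_tr, net_p, config.min_weight
                )
                results[f"density_{sess}"] = network_summary(net_p, config.min_weight).density
        results["peeling"] = peels

    manifest = {
        "version": __version__,
        "animal_id": animal_id,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in config.to_dict().items() if k != "generator"
        },
        "generator": dataclasses.asdict(config.generator),
    }
    _dump(manifest, outdir / "run_manifest.json")
    return results


def run_cohort(config: PipelineConfig, outdir, bundles: list | None = None) -> dict:
    """Per-animal artifacts plus cohort features, classifier, and summaries.

    If *bundles* is None, a synthetic cohort is generated from the config's
    generator parameters and seed. Classification requires >= 4 animals and
    both outcomes; otherwise it is skipped with a warning and the per-animal
    outputs are still written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if bundles is None:
        bundles = simulate_cohort(
            config.n_per_group, seed=config.seed, params=config.generator,
        )
    reports, records = {}, {}
    group_values: dict = {}
    for b in bundles:
        record = b.record if isinstance(b, SessionBundle) else b["record"]
        res = run_animal(config, b, outdir / record.animal_id)
        rep = res.get("training_vs_test")
        if rep is None:
            continue
        reports[record.animal_id] = rep
        records[record.animal_id] = record
        group_values.setdefault(record.group, []).append(rep)

    summary_rows = []
    for grp, reps in sorted(group_values.items()):
        row: dict = {"group": grp, "n": len(reps)}
        for metric in ("jaccard", "turnover", "cosine", "mean_edge_turnover_ti",
                       "survival_rate", "loss_rate", "gain_rate"):
            vals = np.array([getattr(r, metric) for r in reps], dtype=float)
            row[f"{metric}_mean"] = float(vals.mean())
            row[f"{metric}_sem"] = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        summary_rows.append(row)
    _dump(summary_rows, outdir / "cohort_summary.json")

    out = {"summary": summary_rows, "reports": reports}
    outcomes = {records[a].outcome for a in records}
    if len(reports) >= 4 and len(outcomes) == 2:
        fm = assemble_features(reports, records)
        np.savetxt(
            outdir / "feature_matrix.csv",
            fm.X,
            delimiter=",",
            header=",".join(
                ("jaccard", "turnover", "mean_per_neuron_ti", "survival_rate", "loss_rate", "gain_rate")
            ),
            comments="",
        )
        clf = loocv_classify(
            fm,
            l1_ratio=config.l1_ratio,
            reg_strength=config.reg_strength,
            seed=config.seed,
            leakage_mode=config.leakage_mode,
        )
        clf.write_json(outdir / "classifier_report.json")
        fpr, tpr, thr = clf.roc
        np.savetxt(
            outdir / "roc_points.csv",
            np.column_stack([fpr, tpr]),
            delimiter=",",
            header="fpr,tpr",
            comments="",
        )
        out["features"] = fm
        out["classifier"] = clf
    else:
        log.warning(
            "classification skipped: %d animals with reports, outcomes=%s",
            len(reports), sorted(o for o in outcomes if o),
        )
    return out
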