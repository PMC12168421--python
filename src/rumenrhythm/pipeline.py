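"""End-to-end pipeline: simulate -> fit -> classify -> quantify -> ferment -> network.

``run_pipeline`` executes the stages in order from a single declarative
configuration (a dict, or a YAML file path via the CLI), writes every stage's
TSV outputs plus a machine-readable run manifest, and is deterministic: one
seed drives all stochastic stages through independent derived substreams, so
rerunning with the same config and seed reproduces byte-identical outputs.

Configuration keys (all optional except ``outdir``):

* ``seed``: master seed (default 0).
* ``outdir``: output directory.
* ``simulate``: study-design fields (n_cows, clock_times, n_days, n_taxa,
  noise_sd, cow_effect_sd, groups, kingdoms) plus ``class_mix``; when absent,
  ``inputs`` must name abundance/metadata TSV paths.
* ``contrasts``: list of contrast names (default both).
* ``alpha``, ``window``: classification thresholds.
* ``network``: ``groups``, ``r_threshold``, ``p_threshold``, ``n_boot``,
  ``min_mean_abundance`` (taxon prevalence filter for network input).
* ``mantel``: ``permutations``, ``method``, ``group``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import FEEDING_CONTRAST, RFT_CONTRAST, classify_table, summarize_classes
from .errors import ConfigurationError
from .fermentation import fermentation_stats
from .io import AbundanceTable, read_abundance_table, read_metadata, write_abundance_table, write_metadata, write_tsv
from .network import (
    bray_curtis,
    build_network,
    detect_modules,
    levins_niche_breadth,
    mantel,
    node_features,
    sparcc_bootstrap,
    zi_pi,
)
from .quantify import eaa_table, chao1, shannon
from .synthetic import StudyDesign, generate_study

__all__ = ["run_pipeline", "DEFAULT_CONFIG"]

_CONTRAST_GROUPS = {FEEDING_CONTRAST: ("DF", "NF"), RFT_CONTRAST: ("RFT2d", "RFT7d")}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "n_cows": 12,
        "clock_times": [2.0, 8.0, 14.0, 20.0],
        "n_days": 2,
        "n_taxa": 30,
        "noise_sd": 0.25,
        "cow_effect_sd": 0.3,
        "kingdoms": ["bacteria"],
        "class_mix": {"FTR": 8, "MFR": 4, "CCR": 3, "InCCR": 3, "GCR": 3, "LCR": 3, "ARRHYTHMIC": 6},
    },
    "contrasts": [FEEDING_CONTRAST, RFT_CONTRAST],
    "alpha": 0.05,
    "window": [9.0, 15.0],
    "network": {"groups": ["DF", "NF"], "r_threshold": 0.3, "p_threshold": 0.05, "n_boot": 20},
    "mantel": {"permutations": 999, "method": "spearman", "group": "DF"},
}


def _group_table(table: pd.DataFrame, metadata: pd.DataFrame, group: str) -> tuple[pd.DataFrame, np.ndarray]:
    meta = metadata[metadata["group"] == group]
    if meta.empty:
        raise ConfigurationError(f"no samples for group {group!r}")
    sub = table.loc[meta["sample_id"]]
    return sub, meta["clock_time"].to_numpy(dtype=float)


def run_pipeline(config: dict, outdir=None) -> dict:
    """Run the configured stages; returns a result bundle of in-memory frames."""
    cfg = {**DEFAULT_CONFIG, **config}
    outdir = Path(outdir or cfg.get("outdir") or ".")
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    contrasts = list(cfg.get("contrasts", []))
    for c in contrasts:
        if c not in _CONTRAST_GROUPS:
            raise ConfigurationError(f"unknown contrast {c!r}")

    results: dict = {}

    # --- inputs: simulate or load ------------------------------------------
    if "simulate" in cfg and cfg["simulate"]:
        sim = dict(cfg["simulate"])
        kingdoms = tuple(sim.pop("kingdoms", ("bacteria",)))
        class_mix = {k: int(v) for k, v in sim.pop("class_mix").items()}
        design_fields = {
            k: sim[k]
            for k in ("n_cows", "n_days", "n_taxa", "noise_sd", "cow_effect_sd")
            if k in sim
        }
        if "clock_times" in sim:
            design_fields["clock_times"] = tuple(float(t) for t in sim["clock_times"])
        if "groups" in sim:
            design_fields["groups"] = tuple(sim["groups"])
        design = StudyDesign(seed=seed, **design_fields)
        study = generate_study(design, class_mix, kingdoms=kingdoms)
        results["study"] = study
        abundance = {k: t.data for k, t in study.abundance.items()}
        metadata = study.metadata
        qpcr = study.qpcr
        fermentation = study.fermentation
        for k, tab in study.abundance.items():
            write_abundance_table(tab, outdir / f"abundance_{k}.tsv")
            write_tsv(
                study.latent[k].reset_index(),
                outdir / f"latent_{k}.tsv",
                units="latent log-abundance (dimensionless)",
            )
        write_metadata(metadata, outdir / "metadata.tsv")
        write_tsv(qpcr, outdir / "qpcr.tsv", units="total_copies_per_ml: marker-gene copies per mL rumen fluid")
        write_tsv(fermentation, outdir / "fermentation.tsv", units="VFAs mM; ph unitless; nh3n mg/dL")
        write_tsv(study.truth_frame(), outdir / "truth.tsv", units="latent-scale cosinor truth")
    else:
        inputs = cfg.get("inputs")
        if not inputs or "abundance" not in inputs or "metadata" not in inputs:
            raise ConfigurationError("config needs either a 'simulate' block or 'inputs' paths")
        abundance = {
            k: read_abundance_table(p).data for k, p in dict(inputs["abundance"]).items()
        }
        metadata = read_metadata(inputs["metadata"])
        qpcr = pd.read_csv(inputs["qpcr"], sep="\t", comment="#") if inputs.get("qpcr") else None
        fermentation = (
            pd.read_csv(inputs["fermentation"], sep="\t", comment="#")
            if inputs.get("fermentation")
            else None
        )

    missing = set(np.concatenate([t.index.to_numpy() for t in abundance.values()])) - set(
        metadata["sample_id"]
    )
    if missing:
        raise ConfigurationError(f"abundance samples missing from metadata: {sorted(missing)[:5]}")

    # --- cosinor fits + classification ------------------------------------
    alpha = float(cfg.get("alpha", 0.05))
    window = tuple(float(w) for w in cfg.get("window", (9.0, 15.0)))
    # classify_on = "latent" fits the generator's pre-closure series (the
    # scale on which synthetic ground truth is defined); the default fits
    # relative abundance as for real data.  Summaries always use fractions.
    classify_on = cfg.get("classify_on", "abundance")
    if classify_on == "latent":
        if "study" not in results:
            raise ConfigurationError("classify_on='latent' requires a simulate block")
        fit_tables = results["study"].latent
    else:
        fit_tables = abundance
    present_groups = set(metadata["group"])
    class_frames = []
    summaries = []
    for contrast in contrasts:
        ga, gb = _CONTRAST_GROUPS[contrast]
        if not {ga, gb} <= present_groups:
            raise ConfigurationError(
                f"contrast {contrast} needs groups {ga} and {gb}; present: {sorted(present_groups)}"
            )
        for kingdom, table in fit_tables.items():
            sub_a, times_a = _group_table(table, metadata, ga)
            sub_b, times_b = _group_table(table, metadata, gb)
            labels, frame = classify_table(
                sub_a, times_a, sub_b, times_b, contrast, alpha=alpha, window=window
            )
            frame.insert(0, "kingdom", kingdom)
            class_frames.append(frame)
            frac = abundance[kingdom]
            both = frac.loc[sub_a.index.append(sub_b.index)]
            summary = summarize_classes(labels, both).to_frame()
            summary.insert(0, "kingdom", kingdom)
            summary.insert(0, "contrast", contrast)
            summaries.append(summary)
    if class_frames:
        classification = pd.concat(class_frames, ignore_index=True)
        write_tsv(
            classification,
            outdir / "classification.tsv",
            units="peaks/d_peak hours; p-values unitless",
        )
        class_summary = pd.concat(summaries, ignore_index=True)
        write_tsv(class_summary, outdir / "class_summary.tsv", units="mean_abundance_pct: percent of reads")
        results["classification"] = classification
        results["class_summary"] = class_summary

    # --- quantification: EAA + alpha diversity -----------------------------
    if qpcr is not None:
        for kingdom, table in abundance.items():
            totals = (
                qpcr[qpcr["kingdom"] == kingdom]
                .set_index("sample_id")["total_copies_per_ml"]
            )
            if totals.empty:
                continue
            eaa = eaa_table(table, totals)
            write_tsv(
                eaa.reset_index(),
                outdir / f"eaa_{kingdom}.tsv",
                units="estimated absolute abundance, copies per mL",
            )
            results[f"eaa_{kingdom}"] = eaa
    alpha_rows = []
    for kingdom, table in abundance.items():
        for sid, row in table.iterrows():
            alpha_rows.append(
                {"sample_id": sid, "kingdom": kingdom, "shannon": shannon(row.to_numpy())}
            )
    alpha_div = pd.DataFrame(alpha_rows)
    write_tsv(alpha_div, outdir / "alpha_diversity.tsv", units="shannon: bits (log2)")
    results["alpha_diversity"] = alpha_div

    # --- fermentation -------------------------------------------------------
    if fermentation is not None:
        ferm = fermentation_stats(fermentation)
        write_tsv(ferm, outdir / "fermentation_stats.tsv", units="VFAs mM; *_pct percent of TVFA; ech4 mol CH4 per 100 mol TVFA")
        results["fermentation_stats"] = ferm

    # --- networks -----------------------------------------------------------
    net_cfg = dict(cfg.get("network") or {})
    rng_root = np.random.SeedSequence([seed, 7])
    if net_cfg:
        merged = pd.concat(abundance.values(), axis=1)  # union of kingdoms
        kingdom_of = {
            tx: k for k, table in abundance.items() for tx in table.columns
        }
        node_frames = []
        edge_frames = []
        for group, sub_seed in zip(
            net_cfg.get("groups", []), rng_root.spawn(max(1, len(net_cfg.get("groups", []))))
        ):
            sub, _ = _group_table(merged, metadata, group)
            est = sparcc_bootstrap(
                sub,
                n_boot=int(net_cfg.get("n_boot", 100)),
                rng=np.random.default_rng(sub_seed),
            )
            net = build_network(
                est,
                r_threshold=float(net_cfg.get("r_threshold", 0.3)),
                p_threshold=float(net_cfg.get("p_threshold", 0.05)),
                kingdoms=kingdom_of,
            )
            modules, q = detect_modules(net)
            feats = node_features(net)
            roles = zi_pi(net, modules)
            breadth = levins_niche_breadth(sub, pd.Series(
                metadata.set_index("sample_id").loc[sub.index, "after_feeding_h"]
            ))
            bmap = {nb.taxon_id: nb.b for nb in breadth}
            nodes = feats.join(roles.drop(columns=["taxon_id"], errors="ignore"))
            nodes["b_j"] = [bmap.get(tx, np.nan) for tx in nodes.index]
            nodes.insert(0, "group", group)
            nodes.insert(1, "modularity_q", q)
            node_frames.append(nodes.reset_index())
            edges = [
                {"group": group, "taxon_a": a, "taxon_b": b, "r": d["r"],
                 "p": float(est.p.loc[a, b])}
                for a, b, d in net.graph.edges(data=True)
            ]
            edge_frames.append(pd.DataFrame(edges))
        if node_frames:
            write_tsv(pd.concat(node_frames, ignore_index=True), outdir / "network_nodes.tsv",
                      units="zi/pi unitless; b_j niche breadth (1..N)")
            write_tsv(
                pd.concat([e for e in edge_frames if not e.empty], ignore_index=True)
                if any(not e.empty for e in edge_frames)
                else pd.DataFrame(columns=["group", "taxon_a", "taxon_b", "r", "p"]),
                outdir / "network_edges.tsv",
                units="r: SparCC correlation; p: bootstrap",
            )
            results["network_nodes"] = pd.concat(node_frames, ignore_index=True)

    # --- Mantel between kingdoms -------------------------------------------
    man_cfg = dict(cfg.get("mantel") or {})
    if man_cfg and len(abundance) >= 2:
        group = man_cfg.get("group")
        rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
        rows = []
        kingdoms_list = sorted(abundance)
        for i, ka in enumerate(kingdoms_list):
            for kb in kingdoms_list[i + 1 :]:
                ta = abundance[ka]
                tb = abundance[kb]
                if group:
                    ta, _ = _group_table(ta, metadata, group)
                    tb, _ = _group_table(tb, metadata, group)
                r, p = mantel(
                    bray_curtis(ta),
                    bray_curtis(tb),
                    method=man_cfg.get("method", "spearman"),
                    permutations=int(man_cfg.get("permutations", 999)),
                    rng=rng,
                )
                rows.append({"kingdom_a": ka, "kingdom_b": kb, "mantel_r": r, "p": p})
        if rows:
            man = pd.DataFrame(rows)
            write_tsv(man, outdir / "mantel.tsv", units="Bray-Curtis distances; Spearman Mantel")
            results["mantel"] = man

    manifest = {
        "package": "rumenrhythm",
        "version": __version__,
        "seed": seed,
        "config": {k: v for k, v in cfg.items() if k != "outdir"},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    results["manifest"] = manifest
    return results
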