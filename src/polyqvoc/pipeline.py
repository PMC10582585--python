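"""End-to-end orchestration: FASTA + phenotypes -> result tables.

A run reads one or more ortholog FASTA files and an optional phenotype
table, calls the repeats per species (longest-isoform rule), classifies the
calls, runs the configured binned group-mean correlations, and writes:

* ``repeat_calls.csv``   one row per input species, called or flagged
* ``classification.csv`` call-type and ratio-band labels per called species
* ``correlations.csv``   one summary row per correlation plus group rows
* ``run_manifest.json``  config, seed and package versions

Species present in the phenotype table but absent from the FASTA are logged
and excluded from correlations (not fatal).  Every dropped or flagged
species is logged with a reason.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .binstats import SCHEMES, assign_bins, correlate_group_means
from .classify import ClassifierConfig, classify_ratio_band, classify_usv_type
from .errors import FormatError
from .io import OrthologRecord, read_fasta, read_phenotype_table
from .repeats import HingeConfig, select_longest_isoform

logger = logging.getLogger("polyqvoc")


def extract_calls(records: Sequence[OrthologRecord], cfg: HingeConfig) -> pd.DataFrame:
    """Per-species repeat-call table (longest isoform per species).

    Every input species appears exactly once, either called or flagged.
    The printed ratio uses 2 decimals (half-even); flags are ';'-joined.
    """
    by_species: dict[str, list[OrthologRecord]] = {}
    for rec in records:
        by_species.setdefault(rec.species_label, []).append(rec)
    rows = []
    for species, recs in by_species.items():
        rec, call = select_longest_isoform(recs, cfg)
        if not call.ok:
            logger.warning(
                "species %s flagged: %s", species, ";".join(sorted(call.flags))
            )
        rows.append(
            {
                "species": species,
                "gene": rec.gene,
                "sequence_id": rec.sequence_id,
                "q1": call.q1_len,
                "q2": call.q2_len,
                "sum": call.sum_s,
                "ratio": None if call.ratio_r is None else round(call.ratio_r, 2),
                "ratio_full": call.ratio_r,
                "extension_len": call.extension_len,
                "flags": ";".join(sorted(call.flags)),
            }
        )
    return pd.DataFrame(rows)


def classify_calls(
    calls: pd.DataFrame, cfg: ClassifierConfig = ClassifierConfig()
) -> pd.DataFrame:
    """Classification table from a repeat-call table.

    Flagged species (undefined sum/ratio) receive UNASSIGNED labels with the
    flag string as the reason and are excluded from downstream grouping.
    """
    rows = []
    for _, row in calls.iterrows():
        flagged = bool(row["flags"]) or pd.isna(row["ratio_full"])
        s = None if pd.isna(row["sum"]) else int(row["sum"])
        r = None if pd.isna(row["ratio_full"]) else float(row["ratio_full"])
        rows.append(
            {
                "species": row["species"],
                "gene": row["gene"],
                "sum": s,
                "ratio": None if r is None else round(r, 2),
                "usv_type": classify_usv_type(s, r, cfg),
                "foxp2_band": classify_ratio_band(r, "FOXP2_MAMMAL", cfg),
                "foxp1_band": classify_ratio_band(r, "FOXP1", cfg),
                "reasons": row["flags"] if flagged else "",
            }
        )
    return pd.DataFrame(rows)


def correlation_report(
    calls: pd.DataFrame,
    phenotypes: pd.DataFrame,
    scheme_name: str,
    x: str = "ratio",
    y: str = "min_freq_khz",
    bin_on: str = "x",
    transform_x: str = "IDENTITY",
    transform_y: str = "IDENTITY",
) -> pd.DataFrame:
    """One binned group-mean correlation as a tidy report table.

    ``x`` is a repeat metric ('ratio' or 'sum'); ``y`` a phenotype column;
    ``bin_on`` selects which axis the bin scheme applies to.
    """
    scheme = SCHEMES[scheme_name] if isinstance(scheme_name, str) else scheme_name
    called = calls[calls["flags"] == ""].copy()
    called["x"] = called["ratio_full"] if x == "ratio" else called[x]
    merged = called.merge(
        phenotypes.rename(columns={"species_label": "species"}), on="species", how="inner"
    )
    missing = set(phenotypes.get("species", phenotypes.get("species_label", []))) - set(
        called["species"]
    )
    for sp in sorted(missing):
        logger.warning("species %s has phenotypes but no called sequence; excluded", sp)
    bin_values = merged["x"] if bin_on == "x" else merged[y]
    labels = assign_bins(bin_values.tolist(), scheme)
    result, summaries = correlate_group_means(
        merged["x"].tolist(),
        merged[y].tolist(),
        labels,
        transform_x=transform_x,
        transform_y=transform_y,
    )
    rows = [
        {
            "kind": "result",
            "scheme": scheme.name,
            "x": x,
            "y": y,
            "transform_x": transform_x,
            "transform_y": transform_y,
            "n_groups": result.n_groups,
            "r": result.r,
            "p": result.p_value,
            "bin": "",
            "n": int(merged.shape[0]),
            "mean_x": None,
            "mean_y": None,
        }
    ]
    for g in summaries:
        rows.append(
            {
                "kind": "group",
                "scheme": scheme.name,
                "x": x,
                "y": y,
                "transform_x": transform_x,
                "transform_y": transform_y,
                "n_groups": result.n_groups,
                "r": result.r,
                "p": result.p_value,
                "bin": g.bin_label,
                "n": g.n,
                "mean_x": g.mean_x,
                "mean_y": g.mean_y,
            }
        )
    return pd.DataFrame(rows)


def _load_config(config) -> dict:
    if isinstance(config, dict):
        return dict(config)
    text = Path(config).read_text()
    loaded = yaml.safe_load(text)
    if not isinstance(loaded, dict):
        raise FormatError("config must be a key-value mapping")
    return loaded


def run_pipeline(config, out_dir: Optional[str] = None) -> dict[str, Path]:
    """Run extract -> classify -> correlate from a config mapping/YAML path.

    Config keys: ``fasta`` (path or list), ``gene``, ``phenotypes`` (path,
    optional), ``hinge`` / ``classifier`` (parameter overrides, optional),
    ``correlations`` (list of correlation_report kwargs, optional),
    ``out_dir``, ``seed``.
    """
    cfg = _load_config(config)
    out = Path(out_dir or cfg.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    gene = cfg.get("gene", "FOXP2")
    hinge_cfg = HingeConfig(gene=gene, **cfg.get("hinge", {}))
    class_cfg = ClassifierConfig(**cfg.get("classifier", {}))

    fasta_inputs = cfg["fasta"]
    if isinstance(fasta_inputs, str):
        fasta_inputs = [fasta_inputs]
    records: list[OrthologRecord] = []
    for path in fasta_inputs:
        records.extend(read_fasta(path, gene))

    calls = extract_calls(records, hinge_cfg)
    classification = classify_calls(calls, class_cfg)

    outputs: dict[str, Path] = {}
    calls_path = out / "repeat_calls.csv"
    calls.drop(columns=["ratio_full"]).to_csv(calls_path, index=False)
    outputs["repeat_calls"] = calls_path
    class_path = out / "classification.csv"
    classification.to_csv(class_path, index=False)
    outputs["classification"] = class_path

    if cfg.get("phenotypes"):
        pheno_records = read_phenotype_table(cfg["phenotypes"])
        phenotypes = pd.DataFrame(
            [
                {"species": p.species_label, **{
                    k: getattr(p, k)
                    for k in (
                        "char_freq_khz", "min_freq_khz", "max_freq_khz",
                        "bandwidth_khz", "cw_over_bw",
                        "cochlear_height_over_width", "body_mass_g",
                        "max_audible_freq_khz",
                    )
                }}
                for p in pheno_records
            ]
        )
        reports = []
        for corr in cfg.get(
            "correlations",
            [{"scheme_name": "ratio_10bin", "x": "ratio", "y": "min_freq_khz",
              "transform_y": "LOG10"}],
        ):
            reports.append(correlation_report(calls, phenotypes, **corr))
        corr_path = out / "correlations.csv"
        pd.concat(reports, ignore_index=True).to_csv(corr_path, index=False)
        outputs["correlations"] = corr_path

    manifest = {
        "package": "polyqvoc",
        "version": __version__,
        "python": sys.version,
        "seed": cfg.get("seed"),
        "config": {k: v for k, v in cfg.items()},
        "n_species": int(calls.shape[0]),
        "n_flagged": int((calls["flags"] != "").sum()),
    }
    manifest_path = out / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    outputs["manifest"] = manifest_path
    return outputs
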