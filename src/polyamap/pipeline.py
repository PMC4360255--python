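"""Pipeline orchestration: screen -> map -> catalog -> profile -> motifs -> UTR.

A run is a pure function of (transcripts, genome, config): re-execution
yields identical outputs.  Per-stage record counts are logged and written
to a run manifest together with the config and input checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import composition, io, motifs, site_mapper, tail_screen, utr

logger = logging.getLogger("polyamap")


@dataclass
class RunConfig:
    """Tunable parameters of a pipeline run; defaults are the canonical
    screening/mapping thresholds (12-A tail, 100-nt anchor, 201-nt region,
    110-aa ORF minimum)."""

    transcripts: Optional[str] = None
    genome: Optional[str] = None
    outdir: Optional[str] = None
    min_tail: int = 12
    anchor_len: int = 100
    min_orf_aa: int = 110
    k_values: tuple[int, ...] = (4, 5, 6)
    top_n: int = 20
    profile_motifs: tuple[str, ...] = ("AATAAA",)
    keep_multi_locus: bool = True
    pattern_windows: Optional[dict] = None
    flatness_threshold: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_tail < 1 or self.anchor_len < 1 or self.min_orf_aa < 1:
            raise ValueError("numeric parameters must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("k_values", "profile_motifs"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class PipelineResult:
    """Everything one run produces, in memory."""

    sites: list
    stats: dict
    matrix: composition.BaseFrequencyMatrix
    pattern: composition.PatternSummary
    motif_tables: dict
    site_tetramers: pd.DataFrame
    downstream_elements: pd.DataFrame
    profiles: dict
    utr_results: list
    utr_table: pd.DataFrame

    def site_rows(self) -> list[io.SiteTableRow]:
        return [s.to_table_row() for s in self.sites]


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: RunConfig,
    transcripts: Optional[Sequence[io.SequenceRecord]] = None,
    genome: Optional[Sequence[io.SequenceRecord]] = None,
) -> PipelineResult:
    """Execute the full analysis.

    Inputs may be passed in memory or read from the paths in ``config``.
    Stage errors propagate with the stage name prefixed.
    """
    if transcripts is None:
        if not config.transcripts:
            raise ValueError("screen: no transcript input given")
        transcripts = io.read_fasta(config.transcripts)
    if genome is None:
        if not config.genome:
            raise ValueError("map: no genome input given")
        genome = io.read_fasta(config.genome)
    if not transcripts:
        raise ValueError("screen: empty transcript set")

    stats: dict = {"n_input": len(transcripts)}
    tailed, screen_stats = tail_screen.screen_transcripts(
        transcripts, min_tail=config.min_tail, anchor_len=config.anchor_len
    )
    stats.update(
        n_tailed=screen_stats.n_kept,
        n_no_tail=screen_stats.n_no_tail,
        n_short_body=screen_stats.n_short_body,
    )
    deduped = tail_screen.dedupe_by_anchor(tailed)
    stats["n_distinct_anchors"] = len(deduped)

    index = site_mapper.GenomeIndex.from_records(genome)
    regions, map_stats = site_mapper.map_transcripts(
        index, deduped, keep_multi_locus=config.keep_multi_locus
    )
    stats.update(
        n_unmapped=map_stats.n_unmapped,
        n_multi_locus=map_stats.n_multi_locus,
        n_edge_dropped=map_stats.n_edge_dropped,
        n_mapped_regions=map_stats.n_regions,
    )
    sites = site_mapper.catalog_unique_sites(regions)
    stats["n_unique_sites"] = len(sites)
    logger.info(
        "pipeline counts: %s",
        " ".join(f"{k}={v}" for k, v in stats.items()),
    )
    if not sites:
        raise ValueError("catalog: no unique sites mapped")

    matrix = composition.position_base_frequencies(sites)
    pattern = composition.summarize_uauau(
        matrix,
        windows=config.pattern_windows,
        flatness_threshold=config.flatness_threshold,
    )

    motif_tables = {}
    for k, preset in ((6, "hexamer_up50"), (5, "pentamer_up48")):
        if k in config.k_values:
            motif_tables[preset] = motifs.count_sites_with_motif(
                sites, k, motifs.WINDOW_PRESETS[preset]
            )
    site_tetramers = motifs.site_tetramer_distribution(sites)
    downstream = motifs.known_element_scan(sites)
    profiles = {m: motifs.motif_position_profile(sites, m) for m in config.profile_motifs}

    utr_results = [
        utr.compute_utr(t, min_aa=config.min_orf_aa) for t in deduped
    ]
    utr_table = utr.utr_report(utr_results)

    result = PipelineResult(
        sites=sites,
        stats=stats,
        matrix=matrix,
        pattern=pattern,
        motif_tables=motif_tables,
        site_tetramers=site_tetramers,
        downstream_elements=downstream,
        profiles=profiles,
        utr_results=utr_results,
        utr_table=utr_table,
    )
    if config.outdir:
        write_outputs(result, config)
    return result


def write_outputs(result: PipelineResult, config: RunConfig) -> None:
    """Write the TSV report bundle and the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_site_table(result.site_rows(), outdir / "site_table.tsv")
    result.matrix.write_tsv(outdir / "composition_matrix.tsv")
    for name, table in result.motif_tables.items():
        table.sort_values("rank").head(config.top_n * 10).to_csv(
            outdir / f"motifs_{name}.tsv", sep="\t"
        )
    result.site_tetramers.sort_values("rank").to_csv(
        outdir / "motifs_tetramer_at_site.tsv", sep="\t"
    )
    result.downstream_elements.to_csv(outdir / "downstream_elements.tsv", sep="\t")
    for motif, profile in result.profiles.items():
        profile.to_frame().to_csv(outdir / f"profile_{motif}.tsv", sep="\t", index=False)
    result.utr_table.to_csv(outdir / "utr_report.tsv", sep="\t", index=False)
    manifest = {
        "config": {k: v for k, v in asdict(config).items() if not isinstance(v, dict)},
        "stats": result.stats,
        "pattern": {
            "uar_peak": result.pattern.uar.peak_position,
            "second_uur_peak": result.pattern.second_uur.peak_position,
            "site_a_pct": result.pattern.site_a_pct,
            "dur_peak": result.pattern.dur.peak_position,
            "dur_plateau": result.pattern.dur.plateau,
        },
    }
    for key in ("transcripts", "genome"):
        path = getattr(config, key)
        if path and Path(path).exists():
            manifest[f"{key}_sha256"] = _sha256(path)
    cfg_blob = json.dumps(manifest["config"], sort_keys=True, default=str)
    manifest["config_sha256"] = hashlib.sha256(cfg_blob.encode()).hexdigest()
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def compare_runs(
    run_a: PipelineResult,
    run_b: PipelineResult,
    motif: str,
    window: str = "tetramer_at_site",
) -> pd.DataFrame:
    """Two-proportion chi-square on one motif's with-copy counts in two runs."""
    def table_for(run: PipelineResult):
        if window == "tetramer_at_site":
            return run.site_tetramers
        if window not in run.motif_tables:
            raise KeyError(f"run has no motif table for window {window!r}")
        return run.motif_tables[window]

    motif = motif.upper().replace("U", "T")
    ta, tb = table_for(run_a), table_for(run_b)
    xa, na = int(ta.loc[motif, "n_sites_with_copy"]), ta.attrs["n_sites"]
    xb, nb = int(tb.loc[motif, "n_sites_with_copy"]), tb.attrs["n_sites"]
    try:
        stat, p = motifs.two_proportion_chisq(xa, na, xb, nb)
    except ValueError:
        # degenerate margins (motif in all or no sites of both runs): the
        # proportions are equal, the comparison carries no signal
        if xa * nb == xb * na:
            stat, p = 0.0, 1.0
        else:
            raise
    return pd.DataFrame(
        [
            {
                "motif": motif,
                "window": window,
                "x_a": xa,
                "n_a": na,
                "pct_a": 100.0 * xa / na,
                "x_b": xb,
                "n_b": nb,
                "pct_b": 100.0 * xb / nb,
                "chisq": stat,
                "p_value": p,
            }
        ]
    )
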