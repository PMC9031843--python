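"""End-to-end orchestration: normalize -> filter -> DE -> correlate ->
assemble -> seed-filter -> export.

The pipeline consumes per-class count matrices (miRNA, lncRNA, mRNA) over
a shared tumor/normal sample set, normalizes to FPKM, applies the presence
and log2IQR filters, computes differential expression, screens the three
cross-class correlation families with their sign cutoffs, assembles
triplets, and (when transcript sequences or a site table are available)
keeps only triplets with seed-site support on both competing partners.
Every output table carries a provenance header and a run manifest records
thresholds, seed, and input hashes so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .correlate import pairwise_screen
from .de import differential_expression, fpkm_normalize, log2iqr_filter, presence_filter
from .expression import ExpressionMatrix, _write_tsv
from .seedmatch import MatureMiRNA
from .triplets import assemble_triplets, export_network, filter_by_seed_sites


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class PipelineConfig:
    """Thresholds, toggles, and input locations for one run."""

    # inputs (TSV paths); each class needs expr + a shared samples file
    expr_mirna: str | None = None
    expr_lncrna: str | None = None
    expr_mrna: str | None = None
    samples: str | None = None
    sites: str | None = None          # precomputed site table (TSV)
    transcripts_fasta: str | None = None  # or scan sequences directly
    mirna_sequences: dict[str, str] = field(default_factory=dict)

    # thresholds
    log2iqr_threshold: float = 0.5
    presence_fraction: float = 0.70
    cutoff_mi: float = -0.33
    cutoff_lnc_mrna: float = 0.4
    alpha: float = 0.05
    two_sided_lnc_mrna: bool = False

    # stage toggles
    normalize_fpkm: bool = True
    de_restrict: bool = True       # restrict lncRNA/mRNA to significant DE
    upregulated_only: bool = True  # ... and to the upregulated ones
    seed_filter: bool = True       # require binding sites on both partners

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.presence_fraction < 1:
            raise PipelineError("presence_fraction must lie in [0, 1)")
        if self.log2iqr_threshold < 0:
            raise PipelineError("log2iqr_threshold must be >= 0")
        if self.cutoff_mi > 0 or not -1 <= self.cutoff_mi:
            raise PipelineError("cutoff_mi must lie in [-1, 0]")
        if not 0 <= self.cutoff_lnc_mrna <= 1:
            raise PipelineError("cutoff_lnc_mrna must lie in [0, 1]")
        if not 0 < self.alpha < 1:
            raise PipelineError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def provenance(self) -> list[str]:
        items = {
            k: v for k, v in asdict(self).items() if not isinstance(v, dict)
        }
        return [f"cerna {__version__}",
                " ".join(f"{k}={v}" for k, v in sorted(items.items()))]


@dataclass
class PipelineResult:
    de_tables: dict[str, pd.DataFrame]
    pairs: dict[str, pd.DataFrame]
    triplets: pd.DataFrame
    triplets_unfiltered: pd.DataFrame
    sites: pd.DataFrame | None
    manifest: dict


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return inner
    return wrap


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def load_inputs(config: PipelineConfig) -> dict[str, ExpressionMatrix]:
    paths = {
        "miRNA": config.expr_mirna,
        "lncRNA": config.expr_lncrna,
        "mRNA": config.expr_mrna,
    }
    if config.samples is None or any(p is None for p in paths.values()):
        raise PipelineError("stage 'load' failed: expression/sample paths not set")
    return {
        cls: ExpressionMatrix.from_tsv(p, config.samples)
        for cls, p in paths.items()
    }


def run_pipeline(
    config: PipelineConfig,
    matrices: dict[str, ExpressionMatrix] | None = None,
    outdir: str | None = None,
) -> PipelineResult:
    """Execute the full workflow; ``matrices`` bypasses file loading.

    Stages: FPKM normalization; presence and log2IQR filters; per-class
    tumor-vs-normal DE; three pairwise correlation screens; triplet
    assembly; optional seed-site filter; TSV/GraphML export under
    ``outdir`` with a machine-readable manifest.
    """
    input_hashes = {}
    if matrices is None:
        matrices = load_inputs(config)
        input_hashes = {
            k: _sha256(p)
            for k, p in (
                ("expr_mirna", config.expr_mirna),
                ("expr_lncrna", config.expr_lncrna),
                ("expr_mrna", config.expr_mrna),
                ("samples", config.samples),
            )
        }
    for cls, mat in matrices.items():
        if mat.n_features == 0:
            raise PipelineError(f"stage 'load' failed: empty {cls} matrix")

    norm = {
        cls: (fpkm_normalize(m) if config.normalize_fpkm else m)
        for cls, m in matrices.items()
    }

    filtered: dict[str, ExpressionMatrix] = {}
    for cls, mat in norm.items():
        keep = set(presence_filter(mat, config.presence_fraction))
        if cls != "miRNA":  # variance filter applies to the DE screen classes
            keep &= set(log2iqr_filter(mat, config.log2iqr_threshold))
        sub = mat.subset_features(keep)
        if sub.n_features == 0:
            raise PipelineError(
                f"stage 'filter' failed: no {cls} features pass the filters"
            )
        filtered[cls] = sub

    de_tables = {
        cls: _stage("differential_expression")(differential_expression)(
            mat, alpha=config.alpha
        )
        for cls, mat in filtered.items()
    }

    screened = dict(filtered)
    if config.de_restrict:
        for cls in ("lncRNA", "mRNA"):
            de = de_tables[cls]
            keep = de["significant"]
            if config.upregulated_only:
                keep &= de["logFC"] > 0
            sub = screened[cls].subset_features(de.loc[keep, "feature_id"])
            if sub.n_features == 0:
                raise PipelineError(
                    f"stage 'de_restrict' failed: no significant {cls} features"
                )
            screened[cls] = sub

    screen = _stage("correlation_screen")(pairwise_screen)
    pairs = {
        "miRNA-lncRNA": screen(
            screened["miRNA"], screened["lncRNA"], "miRNA-lncRNA",
            cutoff_mi=config.cutoff_mi, alpha=config.alpha,
        ),
        "miRNA-mRNA": screen(
            screened["miRNA"], screened["mRNA"], "miRNA-mRNA",
            cutoff_mi=config.cutoff_mi, alpha=config.alpha,
        ),
        "lncRNA-mRNA": screen(
            screened["lncRNA"], screened["mRNA"], "lncRNA-mRNA",
            cutoff_lnc_mrna=config.cutoff_lnc_mrna, alpha=config.alpha,
            two_sided_lnc_mrna=config.two_sided_lnc_mrna,
        ),
    }

    triplets_all = _stage("triplet_assembly")(assemble_triplets)(
        pairs["miRNA-lncRNA"], pairs["miRNA-mRNA"], pairs["lncRNA-mRNA"]
    )

    sites = None
    triplets = triplets_all
    if config.seed_filter:
        if config.sites:
            sites = pd.read_csv(config.sites, sep="\t", comment="#")
        elif config.transcripts_fasta and config.mirna_sequences:
            from .seedmatch import annotate_fasta

            mirnas = [
                MatureMiRNA(mid, seq)
                for mid, seq in sorted(config.mirna_sequences.items())
            ]
            sites = _stage("seed_scan")(annotate_fasta)(
                mirnas, config.transcripts_fasta
            )
        if sites is not None:
            triplets = _stage("seed_filter")(filter_by_seed_sites)(
                triplets_all, sites
            )

    manifest = {
        "cerna_version": __version__,
        "config": {
            k: v for k, v in asdict(config).items() if k != "mirna_sequences"
        },
        "input_hashes": input_hashes,
        "n_pairs": {k: int(len(v)) for k, v in pairs.items()},
        "n_triplets": int(len(triplets)),
        "n_triplets_before_seed_filter": int(len(triplets_all)),
    }

    result = PipelineResult(de_tables, pairs, triplets, triplets_all, sites, manifest)
    if outdir is not None:
        _write_outputs(result, config, outdir)
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    header = config.provenance()
    for cls, table in result.de_tables.items():
        _write_tsv(table, out / f"de_{cls}.tsv", header)
    all_pairs = pd.concat(result.pairs.values(), ignore_index=True)
    _write_tsv(all_pairs, out / "pairs.tsv", header)
    _write_tsv(result.triplets, out / "triplets.tsv", header)
    if result.sites is not None:
        _write_tsv(result.sites, out / "sites.tsv", header)
    if len(result.triplets):
        export_network(result.triplets, out / "network.graphml", "graphml")
        export_network(result.triplets, out / "network.sif", "sif")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
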