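"""Synthetic tumor/normal cohorts with planted ceRNA structure.

Expression counts are drawn through a Gaussian copula: each planted
lncRNA-miRNA-mRNA triplet gets a 3x3 latent normal correlation matrix whose
entries are calibrated so that the *Spearman* correlations of the emitted
counts hit the requested targets (for a bivariate normal, the population
Spearman rho_s relates to the latent Pearson r by r = 2 sin(pi rho_s / 6)).
Latent normals are mapped through their CDF to uniforms and then through a
negative-binomial quantile function, giving overdispersed counts with the
requested rank correlations. Tumor-vs-normal log2 fold changes are planted
by scaling the negative-binomial mean of tumor samples; dropout (zeroing)
is applied last so it degrades, rather than defines, the planted structure.

The generator also emits transcript sequences with planted canonical miRNA
seed sites (rejection-sampled so no unintended site appears) and paired
qPCR Ct tables with reference genes, so every downstream stage of the
pipeline can be exercised against known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix
from .seedmatch import MatureMiRNA, SITE_TYPES, seed_patterns, scan_transcript

MIRNA_LENGTH_NT = 22
_PSD_TOL = 1e-8


class SimulationError(ValueError):
    """Invalid simulation configuration."""


def spearman_to_pearson(rho_s: float) -> float:
    """Latent Pearson correlation that yields a target Spearman under a
    Gaussian copula: r = 2 sin(pi * rho_s / 6). Odd in rho_s, |r| >= |rho_s|."""
    if not -1.0 < rho_s < 1.0:
        raise SimulationError(f"Spearman target must lie in (-1, 1), got {rho_s}")
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


@dataclass(frozen=True)
class PlantedTriplet:
    """Ground-truth ceRNA triplet with its Spearman targets and logFCs.

    Sign pattern follows the sponge model: the miRNA is negatively
    correlated with both partners (rho_mi_lnc, rho_mi_mrna <= 0) and the
    partners positively with each other (rho_lnc_mrna >= 0).
    """

    lncrna_id: str
    mirna_id: str
    mrna_id: str
    rho_mi_lnc: float = -0.5
    rho_mi_mrna: float = -0.5
    rho_lnc_mrna: float = 0.6
    logfc_lncrna: float = 0.0
    logfc_mirna: float = 0.0
    logfc_mrna: float = 0.0

    def __post_init__(self) -> None:
        if self.rho_mi_lnc > 0 or self.rho_mi_mrna > 0 or self.rho_lnc_mrna < 0:
            raise SimulationError(
                f"triplet {self.key()}: correlation signs must follow the "
                "(-, -, +) ceRNA pattern"
            )
        for r in (self.rho_mi_lnc, self.rho_mi_mrna, self.rho_lnc_mrna):
            if abs(r) >= 1.0:
                raise SimulationError(f"triplet {self.key()}: |rho| must be < 1")

    def key(self) -> tuple[str, str, str]:
        return (self.lncrna_id, self.mirna_id, self.mrna_id)

    def latent_correlation(self) -> np.ndarray:
        """3x3 latent Pearson matrix, order (miRNA, lncRNA, mRNA); raises
        if the converted matrix is not positive semi-definite."""
        r_ml = spearman_to_pearson(self.rho_mi_lnc)
        r_mg = spearman_to_pearson(self.rho_mi_mrna)
        r_lg = spearman_to_pearson(self.rho_lnc_mrna)
        corr = np.array(
            [[1.0, r_ml, r_mg], [r_ml, 1.0, r_lg], [r_mg, r_lg, 1.0]]
        )
        if np.linalg.eigvalsh(corr).min() < -_PSD_TOL:
            raise SimulationError(
                f"triplet {self.key()}: Spearman targets imply a latent "
                "correlation matrix that is not positive semi-definite"
            )
        return corr


@dataclass(frozen=True)
class PlantedSite:
    transcript_id: str
    mirna_id: str
    site_type: str
    start: int | None = None  # 1-based, filled by simulate_sequences
    end: int | None = None


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside the synthetic data."""

    planted_triplets: list[PlantedTriplet]
    feature_logfc: dict[str, float]
    planted_sites: list[PlantedSite] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "planted_triplets": [asdict(t) for t in self.planted_triplets],
            "feature_logfc": self.feature_logfc,
            "planted_sites": [asdict(s) for s in self.planted_sites],
        }


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``n_mirna``/``n_lncrna``/``n_mrna`` are per-class feature totals
    (planted + decoys); when left ``None`` they are derived so that
    ``decoy_fraction`` of the class carries no planted structure.
    ``dispersion`` is the negative-binomial size parameter (variance
    mu + mu^2/dispersion); ``mean_log_expression`` is the log2 of the
    baseline negative-binomial mean.
    """

    n_tumor: int = 46
    n_normal: int = 46
    planted_triplets: list[PlantedTriplet] = field(default_factory=list)
    n_mirna: int | None = None
    n_lncrna: int | None = None
    n_mrna: int | None = None
    decoy_fraction: float = 0.5
    dispersion: float = 5.0
    mean_log_expression: float = 6.0
    dropout_rate: float = 0.0
    mirna_sequences: dict[str, str] = field(default_factory=dict)
    plant_sites: bool = False
    site_type: str = "8mer"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor < 1 or self.n_normal < 1:
            raise SimulationError("need at least one sample per condition")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise SimulationError("dropout_rate must lie in [0, 1)")
        if not 0.0 <= self.decoy_fraction < 1.0:
            raise SimulationError("decoy_fraction must lie in [0, 1)")
        if self.dispersion <= 0:
            raise SimulationError("dispersion must be > 0")
        if self.site_type not in SITE_TYPES:
            raise SimulationError(f"site_type must be one of {SITE_TYPES}")
        ids: list[str] = []
        for t in self.planted_triplets:
            ids += [t.lncrna_id, t.mirna_id, t.mrna_id]
        if len(ids) != len(set(ids)):
            raise SimulationError(
                "planted feature ids must be unique across triplets"
            )
        for attr, planted in (
            ("n_mirna", len({t.mirna_id for t in self.planted_triplets})),
            ("n_lncrna", len({t.lncrna_id for t in self.planted_triplets})),
            ("n_mrna", len({t.mrna_id for t in self.planted_triplets})),
        ):
            n = getattr(self, attr)
            if n is None:
                n = max(1, math.ceil(max(planted, 1) / (1.0 - self.decoy_fraction)))
                setattr(self, attr, n)
            elif n < max(planted, 1):
                raise SimulationError(
                    f"{attr}={n} smaller than the {planted} planted features"
                )


def _nbinom_params(mu: np.ndarray, size: float) -> tuple[float, np.ndarray]:
    return size, size / (size + mu)


def _feature_ids(config: SimulationConfig) -> dict[str, list[str]]:
    planted = {
        "miRNA": [t.mirna_id for t in config.planted_triplets],
        "lncRNA": [t.lncrna_id for t in config.planted_triplets],
        "mRNA": [t.mrna_id for t in config.planted_triplets],
    }
    totals = {"miRNA": config.n_mirna, "lncRNA": config.n_lncrna, "mRNA": config.n_mrna}
    tags = {"miRNA": "mi", "lncRNA": "lnc", "mRNA": "mrna"}
    out = {}
    for cls, ids in planted.items():
        n_decoy = totals[cls] - len(ids)
        out[cls] = ids + [f"dec_{tags[cls]}_{i:04d}" for i in range(1, n_decoy + 1)]
    return out


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[dict[str, ExpressionMatrix], SimulationTruth]:
    """Draw one synthetic cohort.

    Returns one ExpressionMatrix per RNA class (shared sample set: tumor
    columns first, then normal) and the SimulationTruth. Deterministic for
    a fixed config (the config seed drives all randomness).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_tumor + config.n_normal
    sample_ids = [f"T{i:04d}" for i in range(1, config.n_tumor + 1)] + [
        f"N{i:04d}" for i in range(1, config.n_normal + 1)
    ]
    condition = ["tumor"] * config.n_tumor + ["normal"] * config.n_normal
    n_paired = min(config.n_tumor, config.n_normal)
    pair_id = [
        f"P{i + 1:04d}" if i < n_paired else ""
        for grp in (range(config.n_tumor), range(config.n_normal))
        for i in grp
    ]
    sample_meta = pd.DataFrame(
        {"condition": condition, "pair_id": pair_id}, index=pd.Index(sample_ids)
    )
    is_tumor = np.array([c == "tumor" for c in condition])

    ids_by_class = _feature_ids(config)
    feature_logfc: dict[str, float] = {}
    for cls, ids in ids_by_class.items():
        for fid in ids:
            feature_logfc[fid] = 0.0
    for t in config.planted_triplets:
        feature_logfc[t.mirna_id] = t.logfc_mirna
        feature_logfc[t.lncrna_id] = t.logfc_lncrna
        feature_logfc[t.mrna_id] = t.logfc_mrna

    # latent uniforms: correlated blocks for planted triplets, independent
    # for decoys, all drawn in a fixed feature order for determinism
    latent: dict[str, np.ndarray] = {}
    for t in config.planted_triplets:
        corr = t.latent_correlation()
        chol = np.linalg.cholesky(corr + _PSD_TOL * np.eye(3))
        z = rng.standard_normal((n, 3)) @ chol.T
        for j, fid in enumerate((t.mirna_id, t.lncrna_id, t.mrna_id)):
            latent[fid] = z[:, j]
    for cls, ids in ids_by_class.items():
        for fid in ids:
            if fid not in latent:
                latent[fid] = rng.standard_normal(n)

    mu0 = 2.0 ** config.mean_log_expression
    matrices: dict[str, ExpressionMatrix] = {}
    for cls, ids in ids_by_class.items():
        counts = np.empty((len(ids), n))
        for i, fid in enumerate(ids):
            u = stats.norm.cdf(latent[fid])
            mu = np.where(is_tumor, mu0 * 2.0 ** feature_logfc[fid], mu0)
            size, p = _nbinom_params(mu, config.dispersion)
            counts[i] = stats.nbinom.ppf(u, size, p)
        if config.dropout_rate > 0:
            counts[rng.random(counts.shape) < config.dropout_rate] = 0.0
        if cls == "miRNA":
            lengths = np.full(len(ids), MIRNA_LENGTH_NT)
        else:
            lengths = rng.integers(500, 3000, size=len(ids))
        fmeta = pd.DataFrame(
            {"rna_class": cls, "length": lengths}, index=pd.Index(ids, name="feature_id")
        )
        matrices[cls] = ExpressionMatrix(
            pd.DataFrame(counts, index=fmeta.index, columns=sample_ids),
            fmeta,
            sample_meta.copy(),
        )

    sites = []
    if config.plant_sites:
        for t in config.planted_triplets:
            sites.append(PlantedSite(t.lncrna_id, t.mirna_id, config.site_type))
            sites.append(PlantedSite(t.mrna_id, t.mirna_id, config.site_type))
    truth = SimulationTruth(
        planted_triplets=list(config.planted_triplets),
        feature_logfc=feature_logfc,
        planted_sites=sites,
    )
    return matrices, truth


# -- transcript sequences with planted seed sites -----------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _clean_background(rng, length, mirnas, max_tries=10000) -> str:
    """Random DNA with no canonical site (not even a 6mer) for any miRNA."""
    for _ in range(max_tries):
        seq = _random_seq(rng, length)
        if all(not scan_transcript(m, seq) for m in mirnas):
            return seq
    raise SimulationError("could not sample a site-free background sequence")


def simulate_sequences(
    truth: SimulationTruth,
    mirna_sequences: dict[str, str],
    flank_length: int = 50,
    seed: int = 0,
    extra_transcripts: list[str] | None = None,
) -> tuple[dict[str, str], SimulationTruth]:
    """Transcript sequences carrying exactly the planted seed sites.

    Every transcript named in ``truth.planted_sites`` receives exactly one
    site of the requested type at a recorded 1-based position; transcripts
    of planted triplets without a site request (and any
    ``extra_transcripts``) get a site-free background. Backgrounds are
    rejection-sampled so that scanning each emitted sequence against every
    supplied miRNA yields exactly the planted sites and nothing else.

    Returns (sequences, truth) with site positions filled in.
    """
    if flank_length < 8:
        raise SimulationError("flank_length must be at least 8 nt")
    rng = np.random.default_rng(seed)
    mirnas = [MatureMiRNA(mid, seq) for mid, seq in sorted(mirna_sequences.items())]
    by_id = {m.id: m for m in mirnas}

    requested: dict[str, list[PlantedSite]] = {}
    for site in truth.planted_sites:
        if site.mirna_id not in by_id:
            raise SimulationError(
                f"no mature sequence supplied for {site.mirna_id}"
            )
        requested.setdefault(site.transcript_id, []).append(site)

    transcript_ids = list(dict.fromkeys(
        [s.transcript_id for s in truth.planted_sites]
        + [t.lncrna_id for t in truth.planted_triplets]
        + [t.mrna_id for t in truth.planted_triplets]
        + list(extra_transcripts or [])
    ))

    sequences: dict[str, str] = {}
    placed: list[PlantedSite] = []
    for tid in transcript_ids:
        reqs = requested.get(tid, [])
        if not reqs:
            sequences[tid] = _clean_background(rng, 2 * flank_length, mirnas)
            continue
        if len(reqs) > 1:
            raise SimulationError(f"{tid}: at most one planted site per transcript")
        req = reqs[0]
        motif = seed_patterns(by_id[req.mirna_id])[req.site_type]
        for _ in range(10000):
            seq = (
                _random_seq(rng, flank_length)
                + motif
                + _random_seq(rng, flank_length)
            )
            found = {
                m.id: scan_transcript(m, seq, tid) for m in mirnas
            }
            others_clean = all(
                not sites for mid, sites in found.items() if mid != req.mirna_id
            )
            own = found[req.mirna_id]
            if (
                others_clean
                and len(own) == 1
                and own[0].site_type == req.site_type
            ):
                sequences[tid] = seq
                placed.append(
                    PlantedSite(tid, req.mirna_id, req.site_type,
                                own[0].start, own[0].end)
                )
                break
        else:
            raise SimulationError(f"{tid}: rejection sampling failed")
    truth.planted_sites = placed
    return sequences, truth


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for tid, seq in sequences.items():
            fh.write(f">{tid}\n{seq}\n")


# -- paired qPCR Ct tables -----------------------------------------------------

REFERENCE_BASE_CT = {"B2M": 20.0, "RNU48": 22.0, "RNU6": 24.0}


def simulate_ct_table(
    targets: dict[str, tuple[str, float]],
    n_pairs: int = 46,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired tumor/normal Ct measurements with reference genes.

    ``targets`` maps target_id -> (rna_class, planted log2 fold change).
    For normal tissue the target amplifies at its reference level; in tumor
    tissue the target Ct is shifted by -logFC (one extra log2 of template
    halves the threshold cycle). Independent Gaussian technical noise of
    ``noise_sd`` cycles is added to every measured Ct, including references.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for target_id, (rna_class, logfc) in targets.items():
        base = REFERENCE_BASE_CT["B2M" if rna_class != "miRNA" else "RNU48"]
        for i in range(1, n_pairs + 1):
            for cond in ("tumor", "normal"):
                shift = -logfc if cond == "tumor" else 0.0
                noise = rng.normal(0.0, noise_sd, size=4) if noise_sd > 0 else np.zeros(4)
                rows.append(
                    {
                        "pair_id": f"P{i:04d}",
                        "target_id": target_id,
                        "target_class": rna_class,
                        "condition": cond,
                        "ct_target": base + shift + noise[0],
                        "ct_B2M": REFERENCE_BASE_CT["B2M"] + noise[1],
                        "ct_RNU48": REFERENCE_BASE_CT["RNU48"] + noise[2],
                        "ct_RNU6": REFERENCE_BASE_CT["RNU6"] + noise[3],
                    }
                )
    return pd.DataFrame(rows)
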