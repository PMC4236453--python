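"""Synthetic study generator: annotation, binding sites, expression compendium
with planted condition-specific regulons, effector-residue profiles, and
growth curves.

The generators emulate the data regime of a compact prokaryotic genome
(~2,400 genes organised into operons on one or more replicons), eight TFs
with overlapping binding-target sets, an expression compendium of ~35
condition sets (6-20 two-colour arrays each, log2 ratios vs a common
reference), and plate-reader growth curves (OD600 every 30 minutes for 96 h
from a starting OD of 0.09, technical duplicates x biological triplicates).

Planted structure: each TF gets a target set (binding sites with peak
p <= 0.01 in the targets' promoter windows); for each planted
(TF, condition set, role) a ``fraction_coupled`` subset of the targets tracks
(activator) or anti-tracks (repressor) the TF's within-set profile with
coupling strength beta, on top of i.i.d. Gaussian noise in log2 space.  The
TF's own profile carries a per-set mean shift plus a within-set gradient so
the fold-change filter is exercised by construction.  A ground-truth sidecar
records everything tests need to assert recovery.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_binding import GENE_COLUMNS, GenomeAnnotation, promoter_window
from .expression_compendium import ExpressionCompendium
from .sequence_divergence import AMINO_ACIDS, PROFILE_LENGTH

ACTIVATOR = "activator"
REPRESSOR = "repressor"

# independent rng streams per generator, all derived from config.seed
_STREAM_ANNOTATION = 1
_STREAM_GROUND_TRUTH = 2
_STREAM_SITES = 3
_STREAM_COMPENDIUM = 4


@dataclass(frozen=True)
class PlantedRegulon:
    tf: str
    condition_set: str
    role: str  # activator | repressor
    beta: float = 0.8
    fraction_coupled: float = 0.75

    def __post_init__(self) -> None:
        if self.role not in (ACTIVATOR, REPRESSOR):
            raise ValueError(f"role must be activator/repressor, got {self.role!r}")
        if not math.isfinite(self.beta):
            raise ValueError("beta must be finite")
        if not 0 < self.fraction_coupled <= 1:
            raise ValueError("fraction_coupled must be in (0, 1]")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated data regime."""

    n_genes: int = 2400
    n_operons: int = 600
    n_tfs: int = 8
    n_condition_sets: int = 35
    arrays_per_set: tuple[int, int] = (6, 20)
    targets_per_tf: tuple[int, int] = (34, 356)
    planted_regulons: list[PlantedRegulon] = field(default_factory=list)
    noise_sd: float = 0.25          # log2-ratio units
    missing_rate: float = 0.02
    set_shift_magnitude: float = 1.0  # per-set mean shift of a TF (log2)
    tf_amplitude: float = 1.0         # within-set gradient half-range (log2)
    tf_noise_sd: float = 0.25
    gene_length_mean: float = 750.0
    gene_length_sd: float = 150.0
    intergenic_gap_mean: float = 150.0
    replicons: tuple[str, ...] = ("chr",)
    replicon_length: int | None = None  # explicit length triggers packing checks
    site_jitter_sd: float = 25.0        # peak-position resolution, bp
    n_decoy_sites_per_tf: int = 5       # sites with p > 0.01
    n_genic_sites_per_tf: int = 5       # small-p sites in gene bodies, off-promoter
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_operons", "n_tfs", "n_condition_sets"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_genes < self.n_operons:
            raise ValueError("n_genes must be >= n_operons")
        lo, hi = self.arrays_per_set
        if not (0 < lo <= hi):
            raise ValueError("arrays_per_set must be a positive (lo, hi) range")
        lo, hi = self.targets_per_tf
        if not (0 < lo <= hi):
            raise ValueError("targets_per_tf must be a positive (lo, hi) range")
        for pr in self.planted_regulons:
            if not isinstance(pr, PlantedRegulon):
                raise TypeError("planted_regulons entries must be PlantedRegulon")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


@dataclass
class GroundTruth:
    """Everything the tests need to assert recovery of planted structure."""

    tf_ids: list[str]
    site_genes: dict[str, set]        # tf -> genes carrying a promoter site
    site_positions: dict[str, dict]   # tf -> {gene: nominal bp position}
    targets: dict[str, set]           # tf -> operon-closed target set
    coupled: dict[tuple[str, str], set]  # (tf, condition_set) -> coupled genes
    roles: dict[tuple[str, str], str]
    condition_sets: list[str] = field(default_factory=list)

    def validate(self) -> None:
        for (tf, cs), genes in self.coupled.items():
            if not genes <= self.targets[tf]:
                raise ValueError(f"coupled genes of ({tf},{cs}) not within targets")
            if self.condition_sets and cs not in self.condition_sets:
                raise ValueError(f"planted regulon names unknown set {cs!r}")


def condition_set_names(n: int) -> list[str]:
    return [f"cs{i:02d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> GenomeAnnotation:
    """Lay out genes in operons along one or more replicons.

    Consecutive genes are separated by exponential gaps with the configured
    mean; operon members share strand and run in transcription order.
    """
    rng = rng if rng is not None else config.rng(_STREAM_ANNOTATION)
    n, k = config.n_genes, config.n_operons
    # random composition of n genes into k operons (each >= 1)
    cuts = np.sort(rng.choice(np.arange(1, n), size=k - 1, replace=False)) \
        if k > 1 else np.array([], dtype=int)
    sizes = np.diff(np.concatenate([[0], cuts, [n]])).astype(int)
    strands = rng.choice(["+", "-"], size=k)
    # assign operons to replicons in contiguous blocks
    n_rep = len(config.replicons)
    rep_of_operon = np.repeat(np.arange(n_rep), math.ceil(k / n_rep))[:k]

    lengths = np.maximum(
        90, rng.normal(config.gene_length_mean, config.gene_length_sd, size=n)
    )
    lengths = (np.round(lengths / 3) * 3).astype(int)
    gaps = np.maximum(1, np.round(
        rng.exponential(config.intergenic_gap_mean, size=n))).astype(int)

    rows = []
    replicon_lengths: dict[str, int] = {}
    gi = 0
    for ri, rep in enumerate(config.replicons):
        pos = 0
        for oi in np.nonzero(rep_of_operon == ri)[0]:
            op_id = f"op{oi + 1:04d}"
            size = sizes[oi]
            strand = strands[oi]
            members = []
            for j in range(size):
                start = pos + gaps[gi]
                end = start + lengths[gi] - 1
                pos = end
                members.append((start, end))
                gi += 1
            # rank 1 = most upstream in transcription direction
            ranks = range(1, size + 1) if strand == "+" else range(size, 0, -1)
            for (start, end), rank in zip(members, ranks):
                gid = f"g{len(rows) + 1:04d}"
                start_codon = start if strand == "+" else end
                op = op_id if size > 1 else None
                rows.append((gid, rep, strand, start, end, start_codon,
                             op, rank if size > 1 else np.nan))
        replicon_lengths[rep] = pos + int(gaps[gi - 1]) if pos else 1000
        if config.replicon_length is not None:
            if pos > config.replicon_length:
                raise ValueError(
                    f"genes do not fit replicon {rep}: need {pos} bp, "
                    f"have {config.replicon_length}")
            replicon_lengths[rep] = config.replicon_length
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    return GenomeAnnotation(genes, replicon_lengths)


# ---------------------------------------------------------------------------
# ground truth + binding sites
# ---------------------------------------------------------------------------

def _window_table(annotation: GenomeAnnotation, upstream: int = 250,
                  downstream: int = 50) -> pd.DataFrame:
    g = annotation.genes
    win = [promoter_window(sc, st, upstream, downstream)
           for sc, st in zip(g["start_codon"], g["strand"])]
    return pd.DataFrame({
        "gene_id": g["gene_id"], "replicon": g["replicon"],
        "lo": [w[0] for w in win], "hi": [w[1] for w in win]})


def _free_position(windows: pd.DataFrame, gene_id: str) -> int | None:
    """A position inside the gene's promoter window but no other gene's window."""
    row = windows.loc[windows["gene_id"] == gene_id].iloc[0]
    others = windows[(windows["replicon"] == row["replicon"])
                     & (windows["gene_id"] != gene_id)]
    centre = (row["lo"] + row["hi"]) // 2
    candidates = sorted(range(int(row["lo"]), int(row["hi"]) + 1),
                        key=lambda p: abs(p - centre))
    olo = others["lo"].values
    ohi = others["hi"].values
    for p in candidates[::10] + candidates:  # coarse sweep first
        if p < 1:
            continue
        if not np.any((olo <= p) & (p <= ohi)):
            return int(p)
    return None


def plant_ground_truth(config: SimulationConfig, annotation: GenomeAnnotation,
                       rng: np.random.Generator | None = None) -> GroundTruth:
    """Choose TFs, site-bearing genes (with collision-free promoter positions),
    operon-closed target sets, and coupled-gene subsets per planted regulon."""
    rng = rng if rng is not None else config.rng(_STREAM_GROUND_TRUTH)
    genes = annotation.genes
    gene_ids = list(genes["gene_id"])
    windows = _window_table(annotation)

    tf_ids = sorted(rng.choice(gene_ids, size=config.n_tfs, replace=False))

    # downstream operon closure lookup
    closure: dict[str, list[str]] = {}
    for op, grp in genes.dropna(subset=["operon_id"]).groupby("operon_id"):
        grp = grp.sort_values("operon_rank")
        ids = list(grp["gene_id"])
        for i, gid in enumerate(ids):
            closure[gid] = ids[i + 1:]

    # shared pool so target sets overlap between TFs
    pool_size = max(config.targets_per_tf[0], min(600, config.n_genes // 4))
    pool = list(rng.choice(gene_ids, size=pool_size, replace=False))

    site_genes: dict[str, set] = {}
    site_positions: dict[str, dict] = {}
    targets: dict[str, set] = {}
    free_cache: dict[str, int | None] = {}
    for tf in tf_ids:
        lo, hi = config.targets_per_tf
        n_sites = int(rng.integers(lo, hi + 1))
        chosen: set = set()
        positions: dict[str, int] = {}
        tgt: set = set()
        n_pool = int(round(0.6 * n_sites))
        candidates = list(rng.permutation(pool))[:n_pool] + \
            list(rng.permutation(gene_ids))
        for gid in candidates:
            if len(tgt) >= n_sites:  # cap the operon-closed target-set size
                break
            if gid in chosen or gid == tf or gid in tgt:
                continue
            members = [gid] + closure.get(gid, [])
            if tf in members:  # keep the TF out of its own target set
                continue
            if gid not in free_cache:
                free_cache[gid] = _free_position(windows, gid)
            pos = free_cache[gid]
            if pos is None:
                continue
            chosen.add(gid)
            positions[gid] = pos
            tgt.update(members)
        site_genes[tf] = chosen
        site_positions[tf] = positions
        targets[tf] = tgt

    coupled: dict[tuple[str, str], set] = {}
    roles: dict[tuple[str, str], str] = {}
    for pr in config.planted_regulons:
        if pr.tf not in targets:
            raise ValueError(f"planted regulon names unknown TF {pr.tf!r}")
        tgt = sorted(targets[pr.tf])
        n_coupled = int(round(pr.fraction_coupled * len(tgt)))
        coupled[(pr.tf, pr.condition_set)] = set(
            rng.choice(tgt, size=n_coupled, replace=False))
        roles[(pr.tf, pr.condition_set)] = pr.role

    gt = GroundTruth(tf_ids=list(tf_ids), site_genes=site_genes,
                     site_positions=site_positions, targets=targets,
                     coupled=coupled, roles=roles,
                     condition_sets=condition_set_names(config.n_condition_sets))
    gt.validate()
    return gt


def generate_binding_sites(config: SimulationConfig,
                           annotation: GenomeAnnotation,
                           ground_truth: GroundTruth,
                           rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Peak list per TF: planted promoter sites (p <= 0.01, jittered by the
    peak-calling resolution), decoy sites with p > 0.01, and small-p sites in
    gene bodies away from any promoter window."""
    rng = rng if rng is not None else config.rng(_STREAM_SITES)
    genes = annotation.genes.set_index("gene_id")
    windows = _window_table(annotation)
    olo = {rep: grp["lo"].values for rep, grp in windows.groupby("replicon")}
    ohi = {rep: grp["hi"].values for rep, grp in windows.groupby("replicon")}

    def in_any_window(rep: str, pos: int) -> bool:
        return bool(np.any((olo[rep] <= pos) & (pos <= ohi[rep])))

    rows = []
    for tf in ground_truth.tf_ids:
        for gid in sorted(ground_truth.site_genes[tf]):
            rep = genes.at[gid, "replicon"]
            nominal = ground_truth.site_positions[tf][gid]
            jitter = rng.normal(0, config.site_jitter_sd) \
                if config.site_jitter_sd > 0 else 0.0
            pos = max(1, int(round(nominal + jitter)))
            p = 10 ** rng.uniform(-6, math.log10(0.01))
            rows.append((tf, rep, pos, float(rng.lognormal(1.0, 0.5)), p))
        for _ in range(config.n_decoy_sites_per_tf):
            rep = str(rng.choice(list(annotation.replicon_lengths)))
            pos = int(rng.integers(1, annotation.replicon_lengths[rep] + 1))
            p = float(rng.uniform(0.011, 1.0))
            rows.append((tf, rep, pos, float(rng.lognormal(0.2, 0.5)), p))
        placed = 0
        attempts = 0
        while placed < config.n_genic_sites_per_tf and attempts < 500:
            attempts += 1
            gid = str(rng.choice(genes.index))
            rep = genes.at[gid, "replicon"]
            pos = int(rng.integers(genes.at[gid, "start"], genes.at[gid, "end"] + 1))
            if in_any_window(rep, pos):
                continue
            p = 10 ** rng.uniform(-6, math.log10(0.01))
            rows.append((tf, rep, pos, float(rng.lognormal(0.5, 0.5)), p))
            placed += 1
    return pd.DataFrame(
        rows, columns=["tf", "replicon", "position", "intensity", "pvalue"])


# ---------------------------------------------------------------------------
# expression compendium
# ---------------------------------------------------------------------------

def generate_compendium(config: SimulationConfig, ground_truth: GroundTruth,
                        rng: np.random.Generator | None = None
                        ) -> ExpressionCompendium:
    """Log2-ratio matrix with planted condition-specific TF-target couplings.

    TF profile in set s: mean shift U(-shift, shift) + amplitude * gradient
    across the set's arrays + Gaussian noise.  Coupled targets in a planted
    (TF, set): sign(role) * beta * centred TF profile + noise_sd Gaussian
    noise.  Everything else is independent noise_sd Gaussian noise.
    """
    rng = rng if rng is not None else config.rng(_STREAM_COMPENDIUM)
    sets = condition_set_names(config.n_condition_sets)
    lo, hi = config.arrays_per_set
    n_arrays_per_set = {cs: int(rng.integers(lo, hi + 1)) for cs in sets}
    arrays: list[str] = []
    manifest_rows = []
    set_cols: dict[str, list[int]] = {}
    for cs in sets:
        cols = []
        for _ in range(n_arrays_per_set[cs]):
            aid = f"A{len(arrays) + 1:04d}"
            arrays.append(aid)
            manifest_rows.append((aid, cs))
            cols.append(len(arrays) - 1)
        set_cols[cs] = cols

    gene_ids = [f"g{i:04d}" for i in range(1, config.n_genes + 1)]
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    X = rng.normal(0.0, config.noise_sd, size=(config.n_genes, len(arrays)))

    planted = {(pr.tf, pr.condition_set): pr for pr in config.planted_regulons}
    for tf in ground_truth.tf_ids:
        ti = gene_index[tf]
        for cs in sets:
            cols = set_cols[cs]
            m = len(cols)
            shift = rng.uniform(-config.set_shift_magnitude,
                                config.set_shift_magnitude)
            gradient = config.tf_amplitude * np.linspace(-1, 1, m)
            z = shift + gradient + rng.normal(0, config.tf_noise_sd, size=m)
            X[ti, cols] = z
            pr = planted.get((tf, cs))
            if pr is not None:
                sign = 1.0 if pr.role == ACTIVATOR else -1.0
                coupled = sorted(ground_truth.coupled[(tf, cs)])
                # couple to the TF's excursion above its within-set minimum:
                # regulated genes sit at baseline when the TF is at its lowest
                # and spread out as it rises, so the across-target dispersion
                # grows with TF level (what the variance-coupling filter tests)
                zc = z - z.min()
                noise = rng.normal(0, config.noise_sd, size=(len(coupled), m))
                for gi, gid in enumerate(coupled):
                    X[gene_index[gid], cols] = sign * pr.beta * zc + noise[gi]

    if config.missing_rate > 0:
        mask = rng.random(X.shape) < config.missing_rate
        X = X.copy()
        X[mask] = np.nan

    matrix = pd.DataFrame(X, index=gene_ids, columns=arrays)
    manifest = pd.Series({aid: cs for aid, cs in manifest_rows})
    return ExpressionCompendium(matrix, manifest)


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthStrainParams:
    """Modified-logistic growth parameters for one strain."""

    K: float          # carrying capacity, OD600 units
    mu_max: float     # max specific growth rate, 1/h
    lag: float        # lag time, h
    od0: float = 0.09

    def __post_init__(self) -> None:
        if self.K <= 0 or self.mu_max <= 0:
            raise ValueError("K and mu_max must be positive")


def logistic_od(t: np.ndarray, params: GrowthStrainParams) -> np.ndarray:
    """Modified (Zwietering-style) logistic in ln(OD/OD0) space.

    y(t) = A / (1 + exp(4*mu_max*(lag - t)/A + 2)) with A = ln(K/od0); the
    maximum of d ln OD/dt equals mu_max, attained at the inflection of the
    ln-curve, and the tangent there crosses y = 0 at t = lag.
    """
    A = math.log(params.K / params.od0)
    y = A / (1 + np.exp(4 * params.mu_max * (params.lag - t) / A + 2))
    return params.od0 * np.exp(y)


def generate_growth_curves(strain_params: dict[str, GrowthStrainParams],
                           noise_sd: float = 0.02,
                           seed: int | np.random.Generator = 0,
                           n_bio: int = 3, n_tech: int = 2,
                           t_max: float = 96.0, dt: float = 0.5,
                           bio_mu_sd: float = 0.0, bio_lag_sd: float = 0.0,
                           bio_K_sd: float = 0.0) -> pd.DataFrame:
    """OD600 time series every ``dt`` h for ``t_max`` h per strain/replicate.

    Noise is multiplicative log-normal (plate readers err proportionally)
    with a floor at OD 0.01; optional biological-replicate parameter jitter
    produces strain-level variance for the comparison statistics.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    t = np.arange(0, t_max + dt / 2, dt)
    rows = []
    for strain in sorted(strain_params):
        base = strain_params[strain]
        for bio in range(1, n_bio + 1):
            p = GrowthStrainParams(
                K=max(1e-3, base.K * math.exp(rng.normal(0, bio_K_sd))
                      if bio_K_sd else base.K),
                mu_max=max(1e-4, base.mu_max + rng.normal(0, bio_mu_sd)
                           if bio_mu_sd else base.mu_max),
                lag=max(0.0, base.lag + rng.normal(0, bio_lag_sd)
                        if bio_lag_sd else base.lag),
                od0=base.od0)
            for tech in range(1, n_tech + 1):
                od = logistic_od(t, p)
                if noise_sd > 0:
                    od = od * np.exp(rng.normal(0, noise_sd, size=t.size))
                od = np.maximum(od, 0.01)
                for ti, oi in zip(t, od):
                    rows.append((strain, bio, tech, float(ti), float(oi)))
    return pd.DataFrame(
        rows, columns=["strain", "bio_rep", "tech_rep", "time_h", "od600"])


# ---------------------------------------------------------------------------
# residue profiles
# ---------------------------------------------------------------------------

def generate_residue_profiles(cluster_spec: dict[str, dict],
                              seed: int | np.random.Generator = 0
                              ) -> dict[str, str]:
    """Nine-residue effector profiles per TF from per-group consensus strings.

    ``cluster_spec`` maps group name -> {"consensus": str9, "members":
    [tf, ...], "n_mutations": int}; each member's profile is the consensus
    with ``n_mutations`` random positions substituted by a different residue.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    profiles: dict[str, str] = {}
    for group in sorted(cluster_spec):
        spec = cluster_spec[group]
        consensus = spec["consensus"]
        if len(consensus) != PROFILE_LENGTH:
            raise ValueError(f"consensus of {group} must have length "
                             f"{PROFILE_LENGTH}")
        bad = set(consensus) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"invalid amino-acid letters {sorted(bad)} "
                             f"in consensus of {group}")
        n_mut = int(spec.get("n_mutations", 0))
        for tf in spec["members"]:
            residues = list(consensus)
            if n_mut > 0:
                pos = rng.choice(PROFILE_LENGTH, size=n_mut, replace=False)
                for p in pos:
                    alternatives = [a for a in AMINO_ACIDS if a != residues[p]]
                    residues[p] = str(rng.choice(alternatives))
            profiles[tf] = "".join(residues)
    return profiles


# ---------------------------------------------------------------------------
# full-study bundle + ground-truth sidecar
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    config: SimulationConfig
    annotation: GenomeAnnotation
    ground_truth: GroundTruth
    sites: pd.DataFrame
    compendium: ExpressionCompendium


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate annotation, ground truth, binding sites and compendium."""
    annotation = generate_annotation(config)
    gt = plant_ground_truth(config, annotation)
    sites = generate_binding_sites(config, annotation, gt)
    compendium = generate_compendium(config, gt)
    return SyntheticStudy(config, annotation, gt, sites, compendium)


def write_ground_truth(gt: GroundTruth, path) -> None:
    payload = {
        "tf_ids": gt.tf_ids,
        "site_genes": {tf: sorted(g) for tf, g in gt.site_genes.items()},
        "site_positions": gt.site_positions,
        "targets": {tf: sorted(g) for tf, g in gt.targets.items()},
        "coupled": {f"{tf}|{cs}": sorted(g)
                    for (tf, cs), g in gt.coupled.items()},
        "roles": {f"{tf}|{cs}": r for (tf, cs), r in gt.roles.items()},
        "condition_sets": gt.condition_sets,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        tf_ids=payload["tf_ids"],
        site_genes={tf: set(g) for tf, g in payload["site_genes"].items()},
        site_positions=payload["site_positions"],
        targets={tf: set(g) for tf, g in payload["targets"].items()},
        coupled={tuple(k.split("|")): set(g)
                 for k, g in payload["coupled"].items()},
        roles={tuple(k.split("|")): r for k, r in payload["roles"].items()},
        condition_sets=payload["condition_sets"],
    )
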