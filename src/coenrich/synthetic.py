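"""Ground-truthed synthetic inputs for the whole pipeline.

Emulates a MudPIT co-enrichment experiment at the PSM level: a random
proteome with a planted bait complex, seven runs (three salt-elution
fractions, two bait-IP and two control-IgG replicates), target/decoy score
distributions around the acceptance thresholds, and three-channel punctum
images with planted colocalization fractions.

Planted complex members carry the co-enrichment signature the classifier
assumes: abundant in the 290 mM fraction and the bait IPs, absent from the
210 mM fraction and the control IPs, and depleted by a >= 8-fold gap in the
350 mM fraction.  Background proteins have condition-independent log-normal
abundances, so they appear in every run and fail both criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coenrichment import ExperimentDesign
from .psm_filter import FilterThresholds, PeptideSpectrumMatch
from .sequence_db import AMINO_ACIDS, ProteinRecord, digest, make_decoy_db, write_fasta

FRACTION_RUNS = ("F210", "F290", "F350")
BAIT_RUNS = ("BAIT1", "BAIT2")
CONTROL_RUNS = ("CTRL1", "CTRL2")
ALL_RUNS = FRACTION_RUNS + BAIT_RUNS + CONTROL_RUNS


@dataclass(frozen=True)
class ScoreModel:
    """Gaussian score model for one PSM class, truncated at zero.

    XCorr is parameterized as an offset from the charge-specific acceptance
    threshold, so the separation between correct and incorrect matches is
    the same at every charge state.
    """

    xcorr_offset_mean: float
    xcorr_offset_sd: float
    deltcn_mean: float
    deltcn_sd: float


@dataclass(frozen=True)
class SimulationConfig:
    n_target_proteins: int = 200
    n_complex_members: int = 5
    protein_length_range: tuple[int, int] = (150, 600)
    #: log-normal (mu, sigma) of background protein abundance, identical in
    #: every condition
    background_abundance: tuple[float, float] = (0.0, 1.0)
    #: log-normal (mu, sigma) of planted member abundance in the conditions
    #: where the complex is present (bait-complex proteins are biochemically
    #: enriched, so they sit in the upper abundance range)
    member_abundance: tuple[float, float] = (1.5, 0.5)
    #: spectra generated per run
    run_depth: int = 2000
    #: fraction of spectra that are incorrect matches: decoy-peptide PSMs
    #: scored near the acceptance thresholds
    decoy_match_rate: float = 0.05
    correct_score: ScoreModel = ScoreModel(0.8, 0.5, 0.25, 0.08)
    incorrect_score: ScoreModel = ScoreModel(0.0, 0.4, 0.08, 0.04)
    charge_probabilities: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.1, 2: 0.6, 3: 0.3}
    )
    #: members' 290 mM : 350 mM abundance ratio is drawn uniformly here
    fold_gap_range: tuple[float, float] = (8.0, 25.0)
    #: tryptic segments copied between proteins so shared-peptide
    #: distribution is actually exercised
    n_shared_segments: int = 20
    #: combined K+R residue frequency (sets tryptic peptide lengths)
    kr_frequency: float = 0.11
    #: peptides shorter than this are never observed as correct matches
    min_observable_length: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.charge_probabilities.values()), 1.0):
            raise ValueError("charge probabilities must sum to 1")
        if self.run_depth <= 0:
            raise ValueError("run_depth must be positive")
        if self.n_complex_members > self.n_target_proteins:
            raise ValueError("more complex members than proteins")
        if not (0 <= self.decoy_match_rate < 1):
            raise ValueError("decoy_match_rate must be in [0, 1)")
        if self.fold_gap_range[0] < 1:
            raise ValueError("fold gap must be >= 1")


@dataclass
class GroundTruth:
    complex_members: set[str]
    #: per-protein per-condition abundance (rows: accessions, cols: runs)
    abundance: pd.DataFrame


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    targets: list[ProteinRecord]
    decoys: list[ProteinRecord]
    truth: GroundTruth
    #: run label -> PSM table with truth columns (correct, source)
    psm_tables: dict[str, pd.DataFrame]
    design: ExperimentDesign = field(default_factory=ExperimentDesign)

    @property
    def database(self) -> list[ProteinRecord]:
        return self.targets + self.decoys

    def psms(self, runs: Sequence[str] | None = None) -> list[PeptideSpectrumMatch]:
        frames = [self.psm_tables[r] for r in (runs or self.psm_tables)]
        return to_psms(pd.concat(frames, ignore_index=True)) if frames else []


def _random_sequence(rng: np.random.Generator, length: int, kr: float) -> str:
    other = [a for a in AMINO_ACIDS if a not in "KR"]
    probs = np.full(20, (1.0 - kr) / 18)
    aa = list(AMINO_ACIDS)
    for res in "KR":
        probs[aa.index(res)] = kr / 2
    return "".join(rng.choice(aa, size=length, p=probs))


def _insert_shared_segments(
    sequences: list[str], n_segments: int, rng: np.random.Generator, min_len: int = 7
) -> list[str]:
    """Copy a fully tryptic peptide from a donor into an acceptor at a
    cleavage boundary, creating genuinely shared peptides."""
    seqs = list(sequences)
    for _ in range(n_segments):
        donor, acceptor = rng.choice(len(seqs), size=2, replace=False)
        rec = ProteinRecord(f"tmp{donor}", seqs[donor])
        peps = [
            dp.sequence
            for dp in digest(rec, 0)
            if len(dp.sequence) >= min_len and dp.sequence[-1] in "KR"
        ]
        if not peps:
            continue
        pep = peps[rng.integers(len(peps))]
        acc_seq = seqs[acceptor]
        # insert after a K/R (not before P) or at the start, keeping the
        # inserted peptide fully tryptic in the acceptor
        sites = [0] + [
            i + 1
            for i in range(len(acc_seq) - 1)
            if acc_seq[i] in "KR" and acc_seq[i + 1] != "P"
        ]
        pos = sites[rng.integers(len(sites))]
        seqs[acceptor] = acc_seq[:pos] + pep + acc_seq[pos:]
    return seqs


def simulate_proteome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[ProteinRecord], GroundTruth]:
    """Random target proteome plus the planted abundance ground truth."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.protein_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_target_proteins)
    seqs = [_random_sequence(rng, int(n), config.kr_frequency) for n in lengths]
    seqs = _insert_shared_segments(seqs, config.n_shared_segments, rng)
    accs = [f"PROT{i:04d}" for i in range(config.n_target_proteins)]
    records = [ProteinRecord(a, s) for a, s in zip(accs, seqs)]

    member_idx = rng.choice(
        config.n_target_proteins, size=config.n_complex_members, replace=False
    )
    members = {accs[i] for i in member_idx}

    mu_b, sd_b = config.background_abundance
    base = rng.lognormal(mu_b, sd_b, size=config.n_target_proteins)
    abundance = pd.DataFrame(
        np.tile(base[:, None], (1, len(ALL_RUNS))), index=accs, columns=list(ALL_RUNS)
    )
    mu_m, sd_m = config.member_abundance
    for i in member_idx:
        a = rng.lognormal(mu_m, sd_m)
        gap = rng.uniform(*config.fold_gap_range)
        acc = accs[i]
        abundance.loc[acc, :] = 0.0
        abundance.loc[acc, "F290"] = a
        abundance.loc[acc, "F350"] = a / gap
        for r in BAIT_RUNS:
            abundance.loc[acc, r] = a
    return records, GroundTruth(complex_members=members, abundance=abundance)


def _sample_scores(
    rng: np.random.Generator,
    model: ScoreModel,
    charges: np.ndarray,
    thresholds: FilterThresholds,
) -> tuple[np.ndarray, np.ndarray]:
    base = np.array([thresholds.xcorr_threshold(int(c)) for c in charges])
    xcorr = np.maximum(
        0.0, base + rng.normal(model.xcorr_offset_mean, model.xcorr_offset_sd, len(charges))
    )
    deltcn = np.clip(rng.normal(model.deltcn_mean, model.deltcn_sd, len(charges)), 0.0, 1.0)
    return xcorr, deltcn


def simulate_run(
    database: Sequence[ProteinRecord],
    abundances: Mapping[str, float] | pd.Series,
    config: SimulationConfig,
    run_id: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One run's PSM table with per-PSM ground-truth labels.

    Spectra are drawn multinomially over proteins with probability
    proportional to abundance times the protein's observable-peptide count,
    then uniformly over that protein's observable (fully tryptic, length
    >= ``min_observable_length``) peptides.  A ``decoy_match_rate`` fraction
    of spectra are incorrect matches: decoy-peptide PSMs (uniform over decoy
    entries, then over that entry's digest peptides of any length) scored
    from the near-threshold model.  Keeping incorrect matches on the decoy
    side mirrors what the decoy half of a concatenated search measures and
    avoids a small-database artifact: with only a few hundred simulated
    entries, uniformly scattered incorrect target matches would plant
    spurious presence calls on specific proteins orders of magnitude more
    often than in a realistically sized search space.
    """
    thresholds = FilterThresholds()
    targets = [r for r in database if not r.is_decoy]
    obs_peps: list[list[str]] = []
    for rec in targets:
        peps = [
            dp.sequence
            for dp in digest(rec, 0)
            if len(dp.sequence) >= config.min_observable_length
        ]
        obs_peps.append(peps)
    weights = np.array(
        [float(abundances.get(r.accession, 0.0)) * len(p) for r, p in zip(targets, obs_peps)]
    )
    cols = ["run_id", "scan_id", "peptide", "charge", "xcorr", "delt_cn", "correct", "source"]
    if weights.sum() <= 0:
        return pd.DataFrame(columns=cols)

    n = config.run_depth
    n_incorrect = rng.binomial(n, config.decoy_match_rate)
    n_correct = n - n_incorrect

    charges_all = np.array(sorted(config.charge_probabilities))
    charge_p = np.array([config.charge_probabilities[c] for c in charges_all])

    peptides: list[str] = []
    sources: list[str] = []
    prot_idx = rng.choice(len(targets), size=n_correct, p=weights / weights.sum())
    for i in prot_idx:
        peps = obs_peps[i]
        peptides.append(peps[rng.integers(len(peps))])
        sources.append(targets[i].accession)

    # incorrect matches: random decoy entry, random digest peptide (any length)
    decoy_entries = [r for r in database if r.is_decoy]
    if n_incorrect and not decoy_entries:
        raise ValueError("decoy_match_rate > 0 requires decoy entries in the database")
    inc_idx = rng.choice(len(decoy_entries), size=n_incorrect) if n_incorrect else []
    for i in inc_idx:
        peps = [dp.sequence for dp in digest(decoy_entries[i], 0)]
        peptides.append(peps[rng.integers(len(peps))])
        sources.append(decoy_entries[i].accession)

    charges = rng.choice(charges_all, size=n, p=charge_p)
    xc_c, dc_c = _sample_scores(rng, config.correct_score, charges[:n_correct], thresholds)
    xc_i, dc_i = _sample_scores(rng, config.incorrect_score, charges[n_correct:], thresholds)
    xcorr = np.concatenate([xc_c, xc_i])
    deltcn = np.concatenate([dc_c, dc_i])
    correct = np.concatenate([np.ones(n_correct, bool), np.zeros(n_incorrect, bool)])

    order = rng.permutation(n)
    df = pd.DataFrame(
        {
            "run_id": run_id,
            "scan_id": np.arange(n),
            "peptide": np.array(peptides, dtype=object)[order],
            "charge": charges[order].astype(int),
            "xcorr": np.round(xcorr[order], 4),
            "delt_cn": np.round(deltcn[order], 4),
            "correct": correct[order],
            "source": np.array(sources, dtype=object)[order],
        }
    )
    return df[cols]


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Proteome, decoy database, and all seven runs, deterministic in seed."""
    root = np.random.SeedSequence(config.seed)
    ss_prot, ss_decoy, *ss_runs = root.spawn(2 + len(ALL_RUNS))
    records, truth = simulate_proteome(config, np.random.default_rng(ss_prot))
    decoys = make_decoy_db(records, np.random.default_rng(ss_decoy))
    db = records + decoys
    tables = {}
    for run_id, ss in zip(ALL_RUNS, ss_runs):
        tables[run_id] = simulate_run(
            db, truth.abundance[run_id], config, run_id, np.random.default_rng(ss)
        )
    return SimulatedExperiment(
        config=config, targets=records, decoys=decoys, truth=truth, psm_tables=tables
    )


def to_psms(frame: pd.DataFrame) -> list[PeptideSpectrumMatch]:
    return [
        PeptideSpectrumMatch(
            run_id=str(r.run_id),
            scan_id=int(r.scan_id),
            peptide=str(r.peptide),
            charge=int(r.charge),
            xcorr=float(r.xcorr),
            delt_cn=float(r.delt_cn),
        )
        for r in frame.itertuples(index=False)
    ]


def write_experiment(sim: SimulatedExperiment, outdir: str | Path) -> None:
    """FASTA (targets+decoys), one PSM TSV per run, and ground-truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(sim.database, outdir / "database.fasta")
    for run_id, df in sim.psm_tables.items():
        df.drop(columns=["correct", "source"]).to_csv(
            outdir / f"psms_{run_id}.tsv", sep="\t", index=False
        )
        df.to_csv(outdir / f"truth_psms_{run_id}.tsv", sep="\t", index=False)
    sim.truth.abundance.rename_axis("accession").to_csv(
        outdir / "truth_abundance.tsv", sep="\t"
    )
    pd.Series(sorted(sim.truth.complex_members), name="accession").to_csv(
        outdir / "truth_members.tsv", sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# synthetic three-channel punctum images


@dataclass(frozen=True)
class ImageSimConfig:
    n_images: int = 10
    shape: tuple[int, int] = (256, 256)
    n_puncta: int = 100
    #: fraction of marker puncta that are reference(channel)-positive
    ref_fraction: float = 0.6
    #: third-channel colocalization probability for reference-positive puncta
    p_refpos: float = 0.75
    #: ... and for reference-negative puncta
    p_refneg: float = 0.40
    spot_radius: int = 3
    amplitude: float = 3000.0
    background: float = 100.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.ref_fraction, self.p_refpos, self.p_refneg):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")


def _grid_centers(
    shape: tuple[int, int], n: int, radius: int, rng: np.random.Generator
) -> np.ndarray:
    """Jittered grid placement keeping puncta well separated."""
    ncols = int(np.ceil(np.sqrt(n)))
    cell_y = shape[0] / ncols
    cell_x = shape[1] / ncols
    margin = radius + 2
    jitter = max(min(cell_y, cell_x) / 2 - margin, 0.0)
    centers = []
    for k in range(n):
        gy, gx = divmod(k, ncols)
        cy = (gy + 0.5) * cell_y + rng.uniform(-jitter, jitter)
        cx = (gx + 0.5) * cell_x + rng.uniform(-jitter, jitter)
        centers.append((np.clip(cy, margin, shape[0] - margin),
                        np.clip(cx, margin, shape[1] - margin)))
    return np.array(centers)


def _render(
    shape: tuple[int, int],
    centers: np.ndarray,
    which: np.ndarray,
    cfg: ImageSimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Disk spots on noisy background; returns (uint16 image, per-spot area)."""
    img = rng.normal(cfg.background, cfg.noise_sd, size=shape)
    r = cfg.spot_radius
    areas = np.zeros(len(centers), dtype=int)
    for i, (cy, cx) in enumerate(centers):
        if not which[i]:
            continue
        y0, y1 = max(int(cy) - r - 1, 0), min(int(cy) + r + 2, shape[0])
        x0, x1 = max(int(cx) - r - 1, 0), min(int(cx) + r + 2, shape[1])
        yy, xx = np.mgrid[y0:y1, x0:x1]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        img[y0:y1, x0:x1][disk] += cfg.amplitude
        areas[i] = int(disk.sum())
    return np.clip(img, 0, 65535).astype(np.uint16), areas


def simulate_image_set(
    cfg: ImageSimConfig,
) -> tuple[list[dict[str, np.ndarray]], pd.DataFrame]:
    """Three-channel punctum images with planted colocalization.

    Returns one dict per image with channels ``marker``, ``reference``,
    ``third``, plus a ground-truth table of every punctum's center, channel
    memberships, and rendered marker area.
    """
    rng = np.random.default_rng(cfg.seed)
    images: list[dict[str, np.ndarray]] = []
    rows = []
    for im in range(cfg.n_images):
        centers = _grid_centers(cfg.shape, cfg.n_puncta, cfg.spot_radius, rng)
        marker_on = np.ones(cfg.n_puncta, dtype=bool)
        ref_on = rng.random(cfg.n_puncta) < cfg.ref_fraction
        p = np.where(ref_on, cfg.p_refpos, cfg.p_refneg)
        third_on = rng.random(cfg.n_puncta) < p
        marker, areas = _render(cfg.shape, centers, marker_on, cfg, rng)
        reference, _ = _render(cfg.shape, centers, ref_on, cfg, rng)
        third, _ = _render(cfg.shape, centers, third_on, cfg, rng)
        images.append({"marker": marker, "reference": reference, "third": third})
        for k in range(cfg.n_puncta):
            rows.append(
                {
                    "image": im,
                    "punctum": k,
                    "y": centers[k, 0],
                    "x": centers[k, 1],
                    "ref_positive": bool(ref_on[k]),
                    "third_positive": bool(third_on[k]),
                    "marker_area": int(areas[k]),
                }
            )
    return images, pd.DataFrame(rows)


def write_image_set(
    images: Sequence[Mapping[str, np.ndarray]],
    truth: pd.DataFrame,
    outdir: str | Path,
) -> None:
    """Multi-page 16-bit grayscale TIFF per channel plus the truth table."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for channel in ("marker", "reference", "third"):
        stack = np.stack([im[channel] for im in images])
        tifffile.imwrite(outdir / f"{channel}.tif", stack)
    truth.to_csv(outdir / "truth_puncta.tsv", sep="\t", index=False)
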