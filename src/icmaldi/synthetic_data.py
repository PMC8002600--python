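"""Synthetic intact-cell MALDI-TOF data with known ground truth.

No public raw spectra exist for the treated-cyanobacteria setting this
package targets, so every pipeline stage is exercised on simulated data
with the statistical structure the analysis assumes:

* a random **proteome** (FASTA) whose protein masses span the instrument
  window (m/z 1,000-25,000);
* a ~100-peak **control template** whose peak positions are the average
  [M+H]+ masses of selected proteins — so annotation of synthetic peaks
  is meaningful and recoverable;
* a **treatment model** that deletes template peaks with a probability
  increasing in dose and incubation time (logistic in log-dose plus
  time), and adds novel "stress" peaks at masses of proteins absent from
  the control template (mirroring the appearance of stress-protein
  signals after chemical treatment);
* **replicate emission** with per-peak dropout, m/z jitter, and
  log-normal intensity noise, emulating spot-to-spot variability of the
  20 replicate spectra a consensus profile is built from.

Everything is driven by a single integer seed through a spawned
generator hierarchy, so outputs are byte-identical across runs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .mass_calc import protein_mass, protonated_mass
from .msp_builder import ConsensusPeak, ConsensusProfile
from .spectra_io import Peak, PeakList, ProteinRecord, SampleMeta, merge_duplicate_mz, write_fasta

__all__ = [
    "TreatmentEffectConfig",
    "ControlTemplate",
    "SyntheticTruth",
    "generate_proteome",
    "generate_control_template",
    "expected_loss_probability",
    "expected_gain_count",
    "TreatmentInstance",
    "make_treatment_instance",
    "apply_treatment",
    "emit_replicates",
    "simulate_experiment",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class TreatmentEffectConfig:
    """Generative parameters of the treatment model.

    ``p_loss = logistic(loss_steepness * (log(dose / loss_midpoint_dose)
    + time / time_scale))`` for dose > 0; dose 0 gives the dose->0 limit
    ``p_loss = 0``.  The expected number of novel peaks is
    ``gain_rate * (dose / loss_midpoint_dose) * (time / time_scale)``.
    """

    loss_midpoint_dose: float = 5.0  # µM at which p_loss = 0.5 for time = 0
    loss_steepness: float = 1.5
    time_scale: float = 14.0  # days
    gain_rate: float = 12.0  # expected novel peaks per unit scaled dose*time
    mz_jitter_sd: float = 0.3  # Da, replicate-to-replicate mass error
    replicate_dropout: float = 0.2  # per-peak absence probability per replicate
    intensity_cv: float = 0.3  # log-normal intensity noise
    min_separation_da: float = 5.0  # template / novel peak spacing
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.replicate_dropout <= 1:
            raise ValueError("replicate_dropout must be a probability")
        if self.mz_jitter_sd < 0 or self.intensity_cv < 0:
            raise ValueError("noise magnitudes must be >= 0")


@dataclass(frozen=True)
class ControlTemplate:
    """Control peak template plus everything needed to perturb it."""

    profile: ConsensusProfile
    peak_accessions: tuple[str, ...]  # parallel to profile.peaks
    novel_pool: tuple[tuple[float, str], ...]  # (mz, accession) not in template
    mz_window: tuple[float, float]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one perturbed condition."""

    deleted_mz: tuple[float, ...]
    added_mz: tuple[float, ...]
    p_loss: float
    gain_mean: float


def generate_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (8, 200),
    seed: int = 0,
) -> list[ProteinRecord]:
    """Random protein records (accessions SYN0001...), deterministic
    under ``seed``.  Default lengths put average [M+H]+ roughly across
    the m/z 1,000-25,000 biotyping window."""
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    lo, hi = length_range
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid length range {length_range}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    aas = np.array(list(AA_ALPHABET))
    records = []
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(aas, size=length))
        records.append(
            ProteinRecord(
                accession=f"SYN{i + 1:04d}",
                description="synthetic protein",
                sequence=seq,
            )
        )
    return records


def _spaced_selection(
    candidates: list[tuple[float, str]],
    n: int,
    min_separation: float,
    rng: np.random.Generator,
    forbidden: Sequence[float] = (),
) -> list[tuple[float, str]]:
    """Randomly pick up to ``n`` candidates pairwise >= min_separation
    apart and away from ``forbidden`` positions."""
    order = rng.permutation(len(candidates))
    chosen: list[tuple[float, str]] = []
    taken = sorted(forbidden)
    for k in order:
        mz, acc = candidates[k]
        i = np.searchsorted(taken, mz)
        left_ok = i == 0 or mz - taken[i - 1] >= min_separation
        right_ok = i == len(taken) or taken[i] - mz >= min_separation
        if left_ok and right_ok:
            chosen.append((mz, acc))
            taken.insert(i, mz)
            if len(chosen) == n:
                break
    return chosen


def generate_control_template(
    proteome: Sequence[ProteinRecord],
    n_peaks: int = 100,
    mz_window: tuple[float, float] = (1000.0, 25000.0),
    seed: int = 0,
    intensity_sigma: float = 1.0,
) -> ControlTemplate:
    """Select ``n_peaks`` proteins with average [M+H]+ inside the window
    (pairwise >= ``min_separation_da`` = 5 Da apart, so each template
    peak annotates uniquely) and draw log-normal intensities."""
    lo, hi = mz_window
    if not lo < hi:
        raise ValueError(f"invalid m/z window {mz_window}")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    candidates = []
    for rec in proteome:
        if not rec.mass_computable:
            continue
        mz = protonated_mass(protein_mass(rec.sequence).average, "average")
        if lo <= mz <= hi:
            candidates.append((mz, rec.accession))
    min_sep = 5.0
    chosen = _spaced_selection(candidates, n_peaks, min_sep, rng)
    if len(chosen) < n_peaks:
        raise ValueError(
            f"only {len(chosen)} of {n_peaks} requested template peaks fit the "
            f"window with {min_sep} Da separation; enlarge the proteome or window"
        )
    chosen.sort()
    intensities = rng.lognormal(mean=2.0, sigma=intensity_sigma, size=n_peaks)
    peaks = tuple(
        ConsensusPeak(mz=mz, mean_intensity=float(inten), frequency=1.0)
        for (mz, _), inten in zip(chosen, intensities)
    )
    template_accs = tuple(acc for _, acc in chosen)
    template_mzs = [mz for mz, _ in chosen]
    pool = _spaced_selection(
        [c for c in candidates if c[1] not in set(template_accs)],
        n=len(candidates),
        min_separation=min_sep,
        rng=rng,
        forbidden=template_mzs,
    )
    profile = ConsensusProfile(
        profile_id="control_template",
        peaks=peaks,
        n_source_spectra=1,
        meta=SampleMeta(treatment="control", is_control=True),
    )
    return ControlTemplate(
        profile=profile,
        peak_accessions=template_accs,
        novel_pool=tuple(sorted(pool)),
        mz_window=mz_window,
    )


def expected_loss_probability(dose: float, time: float, cfg: TreatmentEffectConfig) -> float:
    """Per-peak deletion probability; logistic in log-dose + scaled time.
    Non-decreasing in both dose and time; exactly 0 at dose 0."""
    if dose < 0 or time < 0:
        raise ValueError("dose and time must be >= 0")
    if dose == 0:
        return 0.0
    z = cfg.loss_steepness * (math.log(dose / cfg.loss_midpoint_dose) + time / cfg.time_scale)
    return 1.0 / (1.0 + math.exp(-z))


def expected_gain_count(dose: float, time: float, cfg: TreatmentEffectConfig) -> float:
    """Expected number of novel stress peaks for a condition."""
    if dose < 0 or time < 0:
        raise ValueError("dose and time must be >= 0")
    return cfg.gain_rate * (dose / cfg.loss_midpoint_dose) * (time / cfg.time_scale)


@dataclass(frozen=True)
class TreatmentInstance:
    """Latent per-treatment structure shared across the dose x time grid.

    ``vulnerabilities[i]`` is the uniform threshold of template peak i:
    the peak disappears once the condition's loss probability exceeds it,
    so harsher conditions lose a superset of the peaks lost by milder
    ones (the same vulnerable proteins keep disappearing as dose and time
    escalate).  ``pool_order`` orders the novel stress peaks; a condition
    expressing k of them expresses the first k, so gains nest the same
    way.  Marginally each peak is still lost with exactly ``p_loss``.
    """

    vulnerabilities: tuple[float, ...]
    pool_order: tuple[int, ...]
    pool_intensities: tuple[float, ...]


def make_treatment_instance(
    template: ControlTemplate, seed: int = 0
) -> TreatmentInstance:
    rng = np.random.default_rng(np.random.SeedSequence((seed, 5)))
    return TreatmentInstance(
        vulnerabilities=tuple(rng.random(len(template.profile))),
        pool_order=tuple(int(i) for i in rng.permutation(len(template.novel_pool))),
        # a stress protein expresses at a characteristic abundance under
        # the treatment, shared by all conditions that express it
        pool_intensities=tuple(rng.lognormal(mean=1.0, sigma=1.0, size=len(template.novel_pool))),
    )


def apply_treatment(
    template: ControlTemplate,
    dose: float,
    time: float,
    cfg: TreatmentEffectConfig,
    seed: int | None = None,
    treatment: str = "treatment",
    instance: TreatmentInstance | None = None,
) -> tuple[ConsensusProfile, SyntheticTruth]:
    """Perturb the control template for one (dose, time) condition.

    Each template peak is deleted when its latent vulnerability falls
    below the logistic loss probability (marginally: an independent
    Bernoulli(p_loss) per peak); a Poisson number of novel stress peaks
    is added at masses of proteins absent from the template (never within
    the spacing margin of any template peak, so differential counts are
    unambiguous).  Dose 0 and time 0 leave the template untouched.
    Passing the same :class:`TreatmentInstance` for several conditions of
    one treatment makes their effects nested along dose and time.
    """
    p_loss = expected_loss_probability(dose, time, cfg)
    gain_mean = expected_gain_count(dose, time, cfg)
    rng = np.random.default_rng(
        np.random.SeedSequence((cfg.seed if seed is None else seed, 2, int(dose * 1000), int(time * 1000)))
    )
    if instance is None:
        instance = TreatmentInstance(
            vulnerabilities=tuple(rng.random(len(template.profile))),
            pool_order=tuple(int(i) for i in rng.permutation(len(template.novel_pool))),
            pool_intensities=tuple(
                rng.lognormal(mean=1.0, sigma=1.0, size=len(template.novel_pool))
            ),
        )
    keep_mask = [u >= p_loss for u in instance.vulnerabilities]
    deleted = tuple(
        p.mz for p, keep in zip(template.profile.peaks, keep_mask) if not keep
    )
    n_gain = min(int(rng.poisson(gain_mean)), len(template.novel_pool)) if gain_mean > 0 else 0
    added = sorted(
        (template.novel_pool[i], instance.pool_intensities[i])
        for i in instance.pool_order[:n_gain]
    )
    added_mz = tuple(mz for (mz, _), _ in added)

    peaks = [p for p, keep in zip(template.profile.peaks, keep_mask) if keep]
    peaks += [
        ConsensusPeak(mz=mz, mean_intensity=float(i), frequency=1.0)
        for (mz, _), i in added
    ]
    peaks.sort(key=lambda p: p.mz)
    if not peaks:
        # pathological total loss; keep the least intense template peak so
        # downstream profile invariants hold
        peaks = [min(template.profile.peaks, key=lambda p: p.mean_intensity)]
        deleted = tuple(mz for mz in deleted if mz != peaks[0].mz)
    profile = ConsensusProfile(
        profile_id=f"{treatment}_{dose:g}uM_{time:g}d",
        peaks=tuple(peaks),
        n_source_spectra=1,
        meta=SampleMeta(treatment=treatment, concentration_uM=dose, time_days=time),
    )
    return profile, SyntheticTruth(
        deleted_mz=deleted, added_mz=added_mz, p_loss=p_loss, gain_mean=gain_mean
    )


def emit_replicates(
    profile: ConsensusProfile,
    n_replicates: int = 20,
    cfg: TreatmentEffectConfig | None = None,
    seed: int | None = None,
) -> list[PeakList]:
    """Simulate replicate spectra of one sample.

    Per replicate, each profile peak is dropped with probability
    ``replicate_dropout``, its m/z jittered Normal(0, mz_jitter_sd), and
    its intensity multiplied by mean-1 log-normal noise of the configured
    CV.  A replicate that loses every peak retains its most intense one
    (an empty spectrum would never be exported by instrument software).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    cfg = cfg or TreatmentEffectConfig()
    rng = np.random.default_rng(
        np.random.SeedSequence((cfg.seed if seed is None else seed, 3))
    )
    sigma = math.sqrt(math.log(1.0 + cfg.intensity_cv**2)) if cfg.intensity_cv > 0 else 0.0
    out = []
    for k in range(n_replicates):
        rows = []
        for p in profile.peaks:
            if rng.random() < cfg.replicate_dropout:
                continue
            mz = p.mz + (rng.normal(0.0, cfg.mz_jitter_sd) if cfg.mz_jitter_sd > 0 else 0.0)
            inten = p.mean_intensity * (
                rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma) if sigma > 0 else 1.0
            )
            rows.append((mz, inten))
        if not rows:
            top = max(profile.peaks, key=lambda q: q.mean_intensity)
            rows = [(top.mz, top.mean_intensity)]
        out.append(
            PeakList(
                spectrum_id=f"{profile.profile_id}_rep{k + 1}",
                peaks=tuple(merge_duplicate_mz(rows)),
                meta=SampleMeta(
                    treatment=profile.meta.treatment,
                    concentration_uM=profile.meta.concentration_uM,
                    time_days=profile.meta.time_days,
                    replicate=k + 1,
                    is_control=profile.meta.is_control,
                ),
            )
        )
    return out


@dataclass(frozen=True)
class SyntheticExperiment:
    """A full simulated treatment study."""

    proteome: tuple[ProteinRecord, ...]
    template: ControlTemplate
    control_replicates: tuple[PeakList, ...]
    treated_replicates: dict  # (treatment, dose, time) -> tuple[PeakList, ...]
    truths: dict  # (treatment, dose, time) -> SyntheticTruth
    config: TreatmentEffectConfig


def simulate_experiment(
    treatments: Sequence[str] = ("azide",),
    doses: Sequence[float] = (1.0, 2.0, 5.0, 10.0),
    times: Sequence[float] = (7.0, 14.0, 21.0),
    n_replicates: int = 20,
    n_proteins: int = 400,
    n_peaks: int = 100,
    cfg: TreatmentEffectConfig | None = None,
    out_dir: str | Path | None = None,
) -> SyntheticExperiment:
    """Generate a complete dose x time grid for one or more treatments.

    With ``out_dir`` set, writes ``proteome.fasta``, per-condition
    replicate peak lists under ``conditions/``, and ``truth.json``.
    """
    cfg = cfg or TreatmentEffectConfig()
    proteome = generate_proteome(n_proteins, seed=cfg.seed)
    template = generate_control_template(proteome, n_peaks=n_peaks, seed=cfg.seed)
    control_reps = emit_replicates(template.profile, n_replicates, cfg, seed=cfg.seed)

    treated: dict = {}
    truths: dict = {}
    for t_i, treatment in enumerate(treatments):
        # one latent vulnerability structure per treatment: conditions of
        # the same treatment lose/gain nested peak sets along dose & time
        instance = make_treatment_instance(template, seed=cfg.seed * 1000 + t_i)
        for dose in doses:
            for time in times:
                cond_seed = int(
                    np.random.SeedSequence(
                        (cfg.seed, 10 + t_i, int(dose * 1000), int(time * 1000))
                    ).generate_state(1)[0] % (2**31)
                )
                perturbed, truth = apply_treatment(
                    template, dose, time, cfg, seed=cond_seed, treatment=treatment,
                    instance=instance,
                )
                reps = emit_replicates(perturbed, n_replicates, cfg, seed=cond_seed + 1)
                treated[(treatment, dose, time)] = tuple(reps)
                truths[(treatment, dose, time)] = truth

    exp = SyntheticExperiment(
        proteome=tuple(proteome),
        template=template,
        control_replicates=tuple(control_reps),
        treated_replicates=treated,
        truths=truths,
        config=cfg,
    )
    if out_dir is not None:
        _write_experiment(exp, Path(out_dir))
    return exp


def _write_experiment(exp: SyntheticExperiment, out_dir: Path) -> None:
    from .spectra_io import write_peaklist

    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(exp.proteome, out_dir / "proteome.fasta")
    cond_dir = out_dir / "conditions"
    ctrl = cond_dir / "control"
    ctrl.mkdir(parents=True, exist_ok=True)
    for k, rep in enumerate(exp.control_replicates, start=1):
        write_peaklist(rep, ctrl / f"rep{k}.txt")
    truth_json = {}
    for (treatment, dose, time), reps in exp.treated_replicates.items():
        d = cond_dir / f"{treatment}_{dose:g}uM_{time:g}d"
        d.mkdir(parents=True, exist_ok=True)
        for k, rep in enumerate(reps, start=1):
            write_peaklist(rep, d / f"rep{k}.txt")
        truth = exp.truths[(treatment, dose, time)]
        truth_json[f"{treatment}|{dose:g}|{time:g}"] = {
            "deleted_mz": list(truth.deleted_mz),
            "added_mz": list(truth.added_mz),
            "p_loss": truth.p_loss,
            "gain_mean": truth.gain_mean,
        }
    (out_dir / "truth.json").write_text(json.dumps(truth_json, indent=1, sort_keys=True))
    (out_dir / "config.json").write_text(json.dumps(asdict(exp.config), indent=1, sort_keys=True))
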