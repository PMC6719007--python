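"""Synthetic NIPT sample generator.

Emulates the statistical structure every estimator in this package relies
on, so the whole pipeline is testable without patient data:

* fragment lengths are a two-component mixture — fetal fragments
  (shorter, default mean 143 bp) mixed into maternal fragments (default
  mean 166 bp) in proportion to the true fetal fraction, so higher-FF
  samples have shorter fragments;
* the chrY read fraction is linear in FF between a female-fetus baseline
  and an adult-male baseline, plus counting noise — inverting that line is
  exactly the Y-based reference estimator;
* a SeqFF-like position-based predictor is provided as a statistical
  surrogate: true FF plus independent noise calibrated to a target
  correlation (default 0.877);
* gestational age, BMI and library concentration are linear-Gaussian in
  standardized FF with target correlations 0.1, -0.33 and -0.22.

Finite sequencing depth is modelled by a multinomial draw of
``fragments_per_sample`` fragments from the mixture; ``analytic_profiles``
replaces the draw with the exact mixture (infinite-depth limit).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

from .fragio import (DEFAULT_LENGTH_RANGE, Dataset, LengthProfile, SampleRecord,
                     write_profile_table)
from .ybase import YBasedParams, estimate_y_based


@dataclass(frozen=True)
class DistSpec:
    """Discretized truncated normal over integer fragment lengths."""

    mean: float
    sd: float

    def pmf(self, length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE) -> np.ndarray:
        lo, hi = length_range
        x = np.arange(lo, hi + 1)
        p = stats.norm.pdf(x, loc=self.mean, scale=self.sd)
        return p / p.sum()


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort (defaults = the conditions
    the estimators are evaluated under; tests use fragments_per_sample=1e4)."""

    n_samples: int = 2000
    fragments_per_sample: int = 500_000
    analytic_profiles: bool = False
    # FF prior: truncated normal
    ff_mean: float = 0.10
    ff_sd: float = 0.04
    ff_bounds: tuple[float, float] = (0.02, 0.30)
    maternal_lengths: DistSpec = field(default_factory=lambda: DistSpec(166.0, 9.0))
    fetal_lengths: DistSpec = field(default_factory=lambda: DistSpec(143.0, 9.0))
    # 10-bp nucleosomal ladder below 150 bp whose intensity reflects FF
    # through its own noise (placental fragmentation intensity varies
    # independently of bulk shortness): a second FF-information channel
    # that per-length-weighted models can combine with the mixture shift
    # but a contiguous unit-weight interval ratio cannot
    ripple_gain: float = 1.5
    ripple_ff_noise_sd: float = 0.03
    ripple_max_length: int = 134
    # between-sample fragmentation variability: per-sample Gaussian shift
    # (bp) applied to both component means; caps how well any length-based
    # estimator can track FF, as in real cohorts
    length_shift_sd: float = 1.5
    # per-sample jitter of the component sds (bp): broadens/narrows both
    # length distributions sample by sample
    length_width_sd: float = 0.8
    # fragmentation heterogeneity: the mixture proportion expressed in the
    # length profile is the true FF plus this Gaussian noise, capping the
    # accuracy of any length-based estimator (chrY still reflects true FF)
    fragmentation_noise_sd: float = 0.025
    # smooth multiplicative batch artifacts: n_batch_modes Gaussian-bump
    # perturbations of the length axis with per-sample N(0, batch_mode_sd)
    # coefficients; a single interval ratio cannot cancel them all, a
    # full-profile linear model largely can
    n_batch_modes: int = 8
    batch_mode_sd: float = 0.05
    # chrY linear model
    chry_female_baseline: float = 0.0002
    chry_male_baseline: float = 0.0020
    chry_noise_sd: float = 2e-5
    # SeqFF surrogate and attribute target correlations
    seqff_rho: float = 0.877
    ga_rho: float = 0.1
    bmi_rho: float = -0.33
    lc_rho: float = -0.22
    ga_mean: float = 14.0
    ga_sd: float = 2.0
    bmi_mean: float = 25.0
    bmi_sd: float = 4.0
    lc_mean: float = 10.0
    lc_sd: float = 3.0
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE
    seed: int = 17

    def __post_init__(self) -> None:
        if not self.fetal_lengths.mean < self.maternal_lengths.mean:
            raise ValueError("fetal mean length must be below maternal mean length")
        for rho in (self.seqff_rho, self.ga_rho, self.bmi_rho, self.lc_rho):
            if not -1.0 < rho < 1.0:
                raise ValueError(f"target correlation {rho} outside (-1, 1)")

    @property
    def ybase_params(self) -> YBasedParams:
        return YBasedParams(self.chry_female_baseline, self.chry_male_baseline)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ff_bounds"] = list(self.ff_bounds)
        d["length_range"] = list(self.length_range)
        return d


def length_mixture(ff: float, maternal: np.ndarray, fetal: np.ndarray) -> np.ndarray:
    """Pointwise mixture ff*fetal + (1-ff)*maternal, renormalized."""
    if not 0.0 <= ff <= 1.0:
        raise ValueError(f"ff={ff} outside [0,1]")
    mix = ff * fetal + (1.0 - ff) * maternal
    return mix / mix.sum()


def noise_sd_for_target_correlation(sd_signal: float, rho: float) -> float:
    """sd of independent Gaussian noise such that corr(signal, signal+noise)
    equals rho: sd_signal * sqrt(1/rho^2 - 1)."""
    if rho <= 0:
        raise ValueError("target correlation must be positive")
    if sd_signal <= 0:
        raise ValueError("signal sd must be positive")
    if rho >= 1.0:
        return 0.0
    return sd_signal * np.sqrt(1.0 / rho ** 2 - 1.0)


def apply_ripple(pmf: np.ndarray, lengths: np.ndarray, amplitude: float,
                 max_length: int = 144) -> np.ndarray:
    """10-bp periodic modulation below ``max_length`` (nucleosomal ladder)."""
    if amplitude == 0.0:
        return pmf
    mod = 1.0 + amplitude * np.cos(2 * np.pi * lengths / 10.0) * (lengths <= max_length)
    out = pmf * mod
    return out / out.sum()


def _correlated_attribute(z: np.ndarray, rho: float, mean: float, sd: float,
                          rng: np.random.Generator) -> np.ndarray:
    """attribute = mean + sd*(rho*z + sqrt(1-rho^2)*eps) for standardized z."""
    eps = rng.standard_normal(z.size)
    return mean + sd * (rho * z + np.sqrt(1.0 - rho ** 2) * eps)


def simulate_dataset(config: SimConfig) -> Dataset:
    """Draw a synthetic cohort; ``true_ff`` is populated on every record and
    ``reference_ff`` is the Y-based estimate from the noisy chrY fraction."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    lo_b, hi_b = config.ff_bounds
    a = (lo_b - config.ff_mean) / config.ff_sd
    b = (hi_b - config.ff_mean) / config.ff_sd
    ff = stats.truncnorm.rvs(a, b, loc=config.ff_mean, scale=config.ff_sd,
                             size=n, random_state=rng)

    lengths = np.arange(config.length_range[0], config.length_range[1] + 1)

    def component_pmfs(shift: float, widen: float) -> tuple[np.ndarray, np.ndarray]:
        mat = DistSpec(config.maternal_lengths.mean + shift,
                       max(config.maternal_lengths.sd + widen, 1.0)
                       ).pmf(config.length_range)
        fet = DistSpec(config.fetal_lengths.mean + shift,
                       max(config.fetal_lengths.sd + widen, 1.0)
                       ).pmf(config.length_range)
        return mat, fet

    maternal, fetal = component_pmfs(0.0, 0.0)
    shifts = (rng.normal(0.0, config.length_shift_sd, size=n)
              if config.length_shift_sd > 0 else np.zeros(n))
    widens = (rng.normal(0.0, config.length_width_sd, size=n)
              if config.length_width_sd > 0 else np.zeros(n))
    ff_len = ff.copy()
    if config.fragmentation_noise_sd > 0:
        ff_len = np.clip(
            ff + rng.normal(0.0, config.fragmentation_noise_sd, size=n), 0.0, 1.0)
    ff_ripple = ff.copy()
    if config.ripple_ff_noise_sd > 0:
        ff_ripple = np.clip(
            ff + rng.normal(0.0, config.ripple_ff_noise_sd, size=n), 0.0, 1.0)

    # fixed bump shapes for this cohort's assay; per-sample coefficients
    k_modes = config.n_batch_modes if config.batch_mode_sd > 0 else 0
    if k_modes > 0:
        centers = rng.uniform(lengths[0] + 10, lengths[-1] - 10, size=k_modes)
        widths_b = rng.uniform(8.0, 25.0, size=k_modes)
        basis = np.exp(-0.5 * ((lengths[None, :] - centers[:, None])
                               / widths_b[:, None]) ** 2)
        mode_coefs = rng.normal(0.0, config.batch_mode_sd, size=(n, k_modes))
    else:
        basis = np.zeros((0, lengths.size))
        mode_coefs = np.zeros((n, 0))

    f0, m1 = config.chry_female_baseline, config.chry_male_baseline
    chry = f0 + ff * (m1 - f0)
    if config.chry_noise_sd > 0:
        chry = chry + rng.normal(0.0, config.chry_noise_sd, size=n)
    chry = np.clip(chry, 0.0, 1.0)
    ref_ff, _ = estimate_y_based(chry, config.ybase_params)

    sd_ff = float(ff.std())
    seqff = ff + rng.normal(
        0.0, noise_sd_for_target_correlation(sd_ff, config.seqff_rho), size=n)
    seqff = np.clip(seqff, 0.0, 1.0)

    z = (ff - ff.mean()) / sd_ff
    ga = _correlated_attribute(z, config.ga_rho, config.ga_mean, config.ga_sd, rng)
    bmi = _correlated_attribute(z, config.bmi_rho, config.bmi_mean, config.bmi_sd, rng)
    lc = _correlated_attribute(z, config.lc_rho, config.lc_mean, config.lc_sd, rng)

    width = len(str(n))
    records = []
    for i in range(n):
        if shifts[i] != 0.0 or widens[i] != 0.0:
            mat_i, fet_i = component_pmfs(shifts[i], widens[i])
        else:
            mat_i, fet_i = maternal, fetal
        mix = length_mixture(ff_len[i], mat_i, fet_i)
        if config.ripple_gain > 0:
            mix = apply_ripple(mix, lengths, config.ripple_gain * ff_ripple[i],
                               config.ripple_max_length)
        if k_modes > 0:
            mix = mix * np.exp(mode_coefs[i] @ basis)
            mix = mix / mix.sum()
        if config.analytic_profiles:
            props = mix
        else:
            counts = rng.multinomial(config.fragments_per_sample, mix)
            props = counts / counts.sum()
        sid = f"S{i + 1:0{width}d}"
        records.append(SampleRecord(
            sample_id=sid,
            profile=LengthProfile(sid, props, config.length_range),
            chry_fraction=float(chry[i]),
            ga=float(ga[i]),
            bmi=float(bmi[i]),
            lc=float(lc[i]),
            seqff_value=float(seqff[i]),
            reference_ff=float(ref_ff[i]),
            true_ff=float(ff[i]),
        ))
    return Dataset(records)


def write_fixture(dataset: Dataset, out_dir: str | Path,
                  config: SimConfig | None = None) -> dict[str, Path]:
    """Write profiles.tsv / attributes.tsv / truth.tsv (+ config echo)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"profiles": out / "profiles.tsv",
             "attributes": out / "attributes.tsv",
             "truth": out / "truth.tsv"}
    write_profile_table(dataset, paths["profiles"])
    with open(paths["attributes"], "w") as fh:
        fh.write("sample_id\tchry_fraction\tga\tbmi\tlc\tseqff_value\treference_ff\n")
        for r in dataset.records:
            fh.write("\t".join([r.sample_id] + [
                "" if v is None else repr(v)
                for v in (r.chry_fraction, r.ga, r.bmi, r.lc,
                          r.seqff_value, r.reference_ff)]) + "\n")
    with open(paths["truth"], "w") as fh:
        fh.write("sample_id\ttrue_ff\n")
        for r in dataset.records:
            fh.write(f"{r.sample_id}\t{'' if r.true_ff is None else repr(r.true_ff)}\n")
    if config is not None:
        paths["config"] = out / "config.yaml"
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return paths


def write_sam_fixture(path: str | Path, fragment_lengths: dict[str, list[int]],
                      seed: int = 17, read_length: int = 35,
                      ref_length: int = 100_000) -> dict[int, int]:
    """Write a tiny paired-end SAM file with the given per-chromosome
    fragment (template) lengths; returns the emitted length tally.

    Every pair is properly paired, primary, MAPQ 60.
    """
    rng = np.random.default_rng(seed)
    path = Path(path)
    chroms = list(fragment_lengths)
    tally: dict[int, int] = {}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for c in chroms:
            fh.write(f"@SQ\tSN:{c}\tLN:{ref_length}\n")
        qi = 0
        for chrom in chroms:
            for tlen in sorted(fragment_lengths[chrom]):
                pos = int(rng.integers(1, ref_length - tlen - 1))
                mpos = pos + tlen - read_length
                qname = f"frag{qi:06d}"
                seq = "A" * read_length
                qual = "I" * read_length
                # 99/147: paired, proper, mate-reverse / reverse, first/second
                fh.write(f"{qname}\t99\t{chrom}\t{pos}\t60\t{read_length}M\t=\t"
                         f"{mpos}\t{tlen}\t{seq}\t{qual}\n")
                fh.write(f"{qname}\t147\t{chrom}\t{mpos}\t60\t{read_length}M\t=\t"
                         f"{pos}\t{-tlen}\t{seq}\t{qual}\n")
                tally[tlen] = tally.get(tlen, 0) + 1
                qi += 1
    return tally
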