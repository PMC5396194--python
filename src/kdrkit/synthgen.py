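"""Synthetic bioassay, voltage-clamp and sequence data with known ground truth.

Every downstream stage of the package gets a recovery oracle from here:

- :func:`simulate_mortality` draws binomial deaths from a probit
  dose-response with optional control (natural) mortality;
- :func:`simulate_trace` produces sodium-current recordings under the
  100-pulse tail-current protocol from a deterministic m3h gating model in
  which a known fraction of channels is pyrethroid-modified, returning the
  closed-form expected M alongside the trace;
- :func:`simulate_vc_experiment` ties the modified fraction to concentration
  through a Hill curve so that full trace -> M -> Hill pipelines can be
  checked against a planted EC50;
- :func:`generate_strain_pair` and :func:`generate_genotype_panel` plant
  synonymous/nonsynonymous changes and diploid genotypes into a synthetic
  sodium-channel open reading frame.

Gating model
------------
Unmodified channels follow deterministic m^3 h kinetics with Boltzmann steady
states and bell-shaped voltage-dependent time constants; the command voltage
is piecewise constant, so m and h relax mono-exponentially within each
segment (no ODE solver is needed).  Deactivation of unmodified channels at
-120 mV has tau ~ 0.1 ms, well below the 0.3-ms blanking window.  Modified
channels open to the same peak open-probability as the unmodified transient
peak, accumulate over the depolarized time of the train (time constant
``tau_build`` of cumulative depolarization: after 100 x 5 ms the buildup
factor is 1 within ~2e-9), are held open across the brief 5-ms interpulse
gaps (tau_slow >> 5 ms), and deactivate with ``tau_slow`` in the final
repolarization window.  The tail/peak chord-conductance ratio therefore reads
out the modified fraction directly and the closed-form expectation is
``expected_M = 100 * f * (1 - exp(-total_depolarized_ms / tau_build))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .ephys import CurrentTrace, VoltageProtocol
from .kdrseq import _CODON_TABLE, IUPAC_FROM_BASES, CodingSequence

__all__ = [
    "MortalitySimSpec",
    "ChannelSimSpec",
    "SequenceSimSpec",
    "GenotypePanel",
    "VCRecord",
    "simulate_mortality",
    "simulate_trace",
    "simulate_vc_experiment",
    "simulate_iv_curve",
    "generate_strain_pair",
    "generate_genotype_panel",
    "default_template_cds",
    "tail_noise_scale",
]


# --------------------------------------------------------------------------
# bioassay mortality
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MortalitySimSpec:
    """Design of a binomial probit concentration-mortality experiment.

    Defaults mirror a typical larval bioassay: five replicates of 25 larvae
    per concentration, concentrations spanning 5-95% mortality.
    """

    true_lc50: float
    true_slope: float
    concentrations: tuple
    n_per_conc: int = 125
    control_mortality: float = 0.0
    n_control: int = 125
    seed: int = 0
    strain: str = "synthetic"
    stage: str = "larvae"
    insecticide: str = "pyrethroid"
    synergist: str = "none"

    def __post_init__(self):
        conc = tuple(float(c) for c in self.concentrations)
        object.__setattr__(self, "concentrations", conc)
        for c in conc:
            if c <= 0:
                raise ValueError(f"non-positive concentration {c!r} in design")
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise ValueError("concentrations must be strictly increasing")
        if self.n_per_conc < 1:
            raise ValueError("n_per_conc must be >= 1")
        if self.true_slope <= 0:
            raise ValueError("true_slope must be positive")
        if self.true_lc50 <= 0:
            raise ValueError("true_lc50 must be positive")
        if not 0.0 <= self.control_mortality < 1.0:
            raise ValueError("control_mortality must lie in [0, 1)")

    @property
    def alpha(self) -> float:
        return -self.true_slope * np.log10(self.true_lc50)

    def mortality(self, concentration) -> np.ndarray:
        """True mortality probability, control mortality mixed in."""
        c = np.asarray(concentration, dtype=float)
        p = stats.norm.cdf(self.alpha + self.true_slope * np.log10(c))
        return self.control_mortality + (1.0 - self.control_mortality) * p


def design_spanning(true_lc50, true_slope, p_lo=0.05, p_hi=0.95, k=5) -> tuple:
    """Concentrations at probit-equispaced quantiles spanning [p_lo, p_hi]."""
    z = np.linspace(stats.norm.ppf(p_lo), stats.norm.ppf(p_hi), k)
    return tuple(true_lc50 * 10.0 ** (z / true_slope))


def simulate_mortality(spec: MortalitySimSpec) -> pd.DataFrame:
    """Draw a concentration-mortality table (control row at concentration 0).

    Deaths per concentration are Binomial(n, p) with
    p = pi0 + (1 - pi0) * Phi(alpha + beta log10 c); reproducible for a fixed
    seed.
    """
    rng = np.random.default_rng(spec.seed)
    rows = [
        {
            "concentration": 0.0,
            "n_exposed": spec.n_control,
            "n_dead": int(rng.binomial(spec.n_control, spec.control_mortality)),
        }
    ]
    for c in spec.concentrations:
        p = float(spec.mortality(c))
        rows.append(
            {
                "concentration": c,
                "n_exposed": spec.n_per_conc,
                "n_dead": int(rng.binomial(spec.n_per_conc, p)),
            }
        )
    table = pd.DataFrame(rows)
    for col, val in (
        ("strain", spec.strain),
        ("stage", spec.stage),
        ("insecticide", spec.insecticide),
        ("synergist", spec.synergist),
    ):
        table[col] = val
    return table


# --------------------------------------------------------------------------
# voltage-clamp traces
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GatingParams:
    """m3h gating parameter set (Boltzmann steady states, bell-shaped taus)."""

    m_vhalf: float = -30.0
    m_k: float = 6.0
    m_tau_base: float = 0.1
    m_tau_amp: float = 0.4
    m_tau_vmid: float = -35.0
    m_tau_vwidth: float = 25.0
    h_vhalf: float = -55.0
    h_k: float = 7.0
    h_tau_base: float = 0.5
    h_tau_amp: float = 8.0
    h_tau_vmid: float = -40.0
    h_tau_vwidth: float = 30.0

    def m_inf(self, v):
        return 1.0 / (1.0 + np.exp(-(v - self.m_vhalf) / self.m_k))

    def tau_m(self, v):
        return self.m_tau_base + self.m_tau_amp * np.exp(
            -(((v - self.m_tau_vmid) / self.m_tau_vwidth) ** 2)
        )

    def h_inf(self, v):
        return 1.0 / (1.0 + np.exp((v - self.h_vhalf) / self.h_k))

    def tau_h(self, v):
        return self.h_tau_base + self.h_tau_amp * np.exp(
            -(((v - self.h_tau_vmid) / self.h_tau_vwidth) ** 2)
        )


@dataclass(frozen=True)
class ChannelSimSpec:
    """World of one oocyte-expression tail-current experiment.

    g_max in uS, potentials in mV, times in ms, currents in uA
    (I = g * (V - E_Na) / 1000).  ``m_max`` (plateau modified percentage),
    ``ec50_true`` and ``hill_true`` define the concentration dependence of the
    modified fraction used by :func:`simulate_vc_experiment`.
    """

    g_max: float = 40.0
    e_na: float = 50.0
    gating: GatingParams = field(default_factory=GatingParams)
    tau_slow: float = 50.0
    tau_build: float = 25.0
    m_max: float = 70.0
    ec50_true: float = 1e-7
    hill_true: float = 1.0
    noise_sd: float = 0.0
    sample_interval: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.m_max <= 100.0:
            raise ValueError("m_max must lie in (0, 100]")
        if self.ec50_true <= 0:
            raise ValueError("ec50_true must be positive")
        if self.sample_interval > 0.1:
            raise ValueError("sample_interval must be <= 0.1 ms")
        tau_deact = float(self.gating.tau_m(-120.0))
        if self.tau_slow < 10.0 * tau_deact:
            raise ValueError(
                "tau_slow must greatly exceed the unmodified deactivation time "
                f"constant ({tau_deact:.3g} ms at -120 mV)"
            )

    def modified_fraction(self, concentration) -> np.ndarray:
        c = np.asarray(concentration, dtype=float)
        ch = c ** self.hill_true
        return (self.m_max / 100.0) * ch / (ch + self.ec50_true ** self.hill_true)


def _check_protocol(protocol: VoltageProtocol, dt: float):
    for dur, _ in protocol.segments():
        n = dur / dt
        if abs(n - round(n)) > 1e-9 or round(n) < 2:
            raise ValueError(
                f"sample interval {dt} ms incommensurate with a {dur} ms "
                "protocol segment"
            )


def _gating_series(protocol: VoltageProtocol, spec: ChannelSimSpec):
    """Sampled m, h, voltage and modified-channel availability over the protocol."""
    g = spec.gating
    dt = spec.sample_interval
    _check_protocol(protocol, dt)
    n_total = int(round(protocol.total_ms / dt))
    m = np.empty(n_total)
    h = np.empty(n_total)
    v_cmd = np.empty(n_total)
    a_mod = np.empty(n_total)

    m0 = float(g.m_inf(protocol.v_hold))
    h0 = float(g.h_inf(protocol.v_hold))
    dep_time = 0.0  # cumulative depolarized ms
    idx = 0
    segs = protocol.segments()
    for seg_no, (dur, v) in enumerate(segs):
        n = int(round(dur / dt))
        tl = np.arange(n) * dt
        m_inf, tau_m = g.m_inf(v), g.tau_m(v)
        h_inf, tau_h = g.h_inf(v), g.tau_h(v)
        m[idx : idx + n] = m_inf + (m0 - m_inf) * np.exp(-tl / tau_m)
        h[idx : idx + n] = h_inf + (h0 - h_inf) * np.exp(-tl / tau_h)
        v_cmd[idx : idx + n] = v
        depolarized = v != protocol.v_hold
        if depolarized:
            a_mod[idx : idx + n] = 1.0 - np.exp(-(dep_time + tl) / spec.tau_build)
            dep_time += dur
        elif seg_no == len(segs) - 1:
            a_end = 1.0 - np.exp(-dep_time / spec.tau_build)
            a_mod[idx : idx + n] = a_end * np.exp(-tl / spec.tau_slow)
        else:
            a_mod[idx : idx + n] = 1.0 - np.exp(-dep_time / spec.tau_build)
        m0 = float(m_inf + (m0 - m_inf) * np.exp(-dur / tau_m))
        h0 = float(h_inf + (h0 - h_inf) * np.exp(-dur / tau_h))
        idx += n
    return m, h, v_cmd, a_mod, dep_time


def peak_open_probability(protocol: VoltageProtocol, spec: ChannelSimSpec) -> float:
    """Peak m^3 h during a single step pulse, on a fine analytic grid."""
    g = spec.gating
    m0 = float(g.m_inf(protocol.v_hold))
    h0 = float(g.h_inf(protocol.v_hold))
    v = protocol.v_step
    t = np.arange(0.0, protocol.pulse_ms, min(spec.sample_interval, 0.002))
    m = g.m_inf(v) + (m0 - g.m_inf(v)) * np.exp(-t / g.tau_m(v))
    h = g.h_inf(v) + (h0 - g.h_inf(v)) * np.exp(-t / g.tau_h(v))
    return float(np.max(m ** 3 * h))


def _trace_basis(protocol: VoltageProtocol, spec: ChannelSimSpec):
    """Noiseless unmodified and unit-modified current components (uA)."""
    m, h, v_cmd, a_mod, dep_time = _gating_series(protocol, spec)
    drive = (v_cmd - spec.e_na) / 1000.0
    p_peak = peak_open_probability(protocol, spec)
    i_unmod = spec.g_max * m ** 3 * h * drive
    i_mod_unit = spec.g_max * p_peak * a_mod * drive
    a_end = 1.0 - np.exp(-dep_time / spec.tau_build)
    return i_unmod, i_mod_unit, a_end


def expected_m(spec: ChannelSimSpec, protocol: VoltageProtocol, modified_fraction) -> float:
    """Closed-form M (%) of the generator model for a given modified fraction."""
    dep_time = protocol.n_pulses * protocol.pulse_ms
    a_end = 1.0 - np.exp(-dep_time / spec.tau_build)
    return float(100.0 * np.asarray(modified_fraction, dtype=float) * a_end)


def simulate_trace(
    protocol: VoltageProtocol,
    spec: ChannelSimSpec,
    modified_fraction: float,
    rng: np.random.Generator | None = None,
    meta: dict | None = None,
):
    """One paired (pre-drug, drug) recording with a known modified fraction.

    Returns ``(trace, expected_m)``: the drug-condition trace (with the paired
    pre-drug recording in ``trace.pre_current``) and the closed-form expected
    M in percent.  Gaussian noise of sd ``spec.noise_sd`` (uA) is added
    independently to both recordings.
    """
    f = float(modified_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"modified_fraction must lie in [0, 1], got {f}")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    i_unmod, i_mod_unit, a_end = _trace_basis(protocol, spec)
    pre = i_unmod.copy()
    post = (1.0 - f) * i_unmod + f * i_mod_unit
    if spec.noise_sd > 0:
        pre = pre + rng.normal(0.0, spec.noise_sd, pre.size)
        post = post + rng.normal(0.0, spec.noise_sd, post.size)
    trace = CurrentTrace(
        sample_interval=spec.sample_interval,
        current=post,
        protocol=protocol,
        meta={"e_na": spec.e_na, "modified_fraction": f, **(meta or {})},
        pre_current=pre,
    )
    return trace, float(100.0 * f * a_end)


@dataclass(frozen=True)
class VCRecord:
    concentration: float
    oocyte: int
    trace: CurrentTrace
    expected_m: float


def tail_noise_scale(spec: ChannelSimSpec, protocol: VoltageProtocol | None = None) -> float:
    """Tail-current amplitude (uA) corresponding to M = m_max.

    Useful to express trace noise as a fraction of the dose-response plateau:
    ``noise_sd = 0.02 * tail_noise_scale(spec)`` is "2% of the plateau" in
    current units.
    """
    protocol = protocol or VoltageProtocol()
    p_peak = peak_open_probability(protocol, spec)
    return float(
        (spec.m_max / 100.0)
        * spec.g_max
        * p_peak
        * abs(protocol.v_hold - spec.e_na)
        / 1000.0
    )


def simulate_vc_experiment(
    spec: ChannelSimSpec,
    concentrations,
    n_oocytes: int,
    protocol: VoltageProtocol | None = None,
    variant: str = "reference",
) -> list:
    """Simulate a dose-response experiment: n_oocytes noisy traces per dose.

    The modified fraction at concentration c is the Hill curve
    ``(m_max/100) * c^h / (c^h + ec50_true^h)``.
    """
    conc = [float(c) for c in concentrations]
    if not conc:
        raise ValueError("empty concentration list")
    if any(c <= 0 for c in conc):
        raise ValueError("concentrations must be positive")
    if n_oocytes < 1:
        raise ValueError("n_oocytes must be >= 1")
    protocol = protocol or VoltageProtocol()
    rng = np.random.default_rng(spec.seed)
    records = []
    for c in conc:
        f = float(spec.modified_fraction(c))
        for oocyte in range(n_oocytes):
            trace, em = simulate_trace(
                protocol,
                spec,
                f,
                rng=rng,
                meta={"concentration": c, "oocyte": oocyte, "variant": variant},
            )
            records.append(
                VCRecord(concentration=c, oocyte=oocyte, trace=trace, expected_m=em)
            )
    return records


def simulate_iv_curve(
    spec: ChannelSimSpec, potentials=None, protocol: VoltageProtocol | None = None
) -> np.ndarray:
    """Peak-current IV relation of the unmodified channel (noiseless)."""
    protocol = protocol or VoltageProtocol()
    if potentials is None:
        potentials = np.arange(-80.0, 75.0, 10.0)
    rows = []
    for v in potentials:
        p = replace(protocol, v_step=float(v)) if v != protocol.v_hold else protocol
        p_peak = peak_open_probability(p, spec)
        rows.append((float(v), spec.g_max * p_peak * (float(v) - spec.e_na) / 1000.0))
    return np.asarray(rows)


# --------------------------------------------------------------------------
# sequences and genotype panels
# --------------------------------------------------------------------------

_CODONS = sorted(_CODON_TABLE)
_SENSE_CODONS = [c for c in _CODONS if _CODON_TABLE[c] != "*"]


def default_template_cds(n_codons: int = 1600) -> str:
    """Bundled synthetic open reading frame standing in for a channel CDS.

    Deterministic (fixed internal seed): starts with ATG, ends with TAA, has
    GTA (Val) at codon 410 and TTC (Phe) at codon 1534, and no internal stop
    codons.  Synthetic: not derived from any real sequence record.
    """
    if n_codons < 1536:
        raise ValueError("template must reach past codon 1534")
    rng = np.random.default_rng(20170419)
    codons = list(rng.choice(_SENSE_CODONS, size=n_codons))
    codons[0] = "ATG"
    codons[409] = "GTA"
    codons[1533] = "TTC"
    codons[-1] = "TAA"
    return "".join(codons)


def synonymous_substitution(codon: str, rng: np.random.Generator) -> str:
    """A single-base synonymous neighbour of ``codon`` (error if none exists)."""
    aa = _CODON_TABLE[codon]
    options = []
    for i in range(3):
        for base in "ACGT":
            if base == codon[i]:
                continue
            alt = codon[:i] + base + codon[i + 1 :]
            if _CODON_TABLE[alt] == aa:
                options.append(alt)
    if not options:
        raise ValueError(f"codon {codon} has no single-base synonymous neighbour")
    return str(rng.choice(sorted(options)))


@dataclass(frozen=True)
class SequenceSimSpec:
    """Plan for a strain CDS pair and a diploid genotype panel.

    Defaults plant the resistance haplotype of the study system: six
    synonymous changes plus V410L (GTA -> TTA) and F1534C (TTC -> TGC), i.e.
    eight nucleotide differences of which two are nonsynonymous.
    ``genotype_config`` maps residue -> per-individual zygosity labels
    ("hom_wild" | "het" | "hom_mutant").
    """

    template_cds: str = ""
    syn_positions: tuple = (200, 500, 800, 1000, 1200, 1400)
    nonsyn_changes: tuple = ((410, "GTA", "TTA"), (1534, "TTC", "TGC"))
    n_individuals: int = 10
    genotype_config: dict = field(
        default_factory=lambda: {
            410: ("hom_mutant",) * 3 + ("het",) * 4 + ("hom_wild",) * 3,
            1534: ("hom_mutant",) * 10,
        }
    )
    offset: int = 0
    seed: int = 0

    def __post_init__(self):
        if not self.template_cds:
            object.__setattr__(self, "template_cds", default_template_cds())
        seq = self.template_cds.upper()
        object.__setattr__(self, "template_cds", seq)
        if len(seq) % 3 != 0:
            raise ValueError("template CDS length must be divisible by 3")
        n_codons = len(seq) // 3
        for res in self.syn_positions:
            if not 1 <= res - self.offset <= n_codons:
                raise ValueError(f"synonymous codon index {res} outside template")
        for res, wild, mut in self.nonsyn_changes:
            idx = res - self.offset
            if not 1 <= idx <= n_codons:
                raise ValueError(f"codon index {res} outside template")
            have = seq[(idx - 1) * 3 : idx * 3]
            if have != wild.upper():
                raise ValueError(
                    f"template codon {res} is {have}, expected wild codon {wild}"
                )
            if mut.upper() == wild.upper():
                raise ValueError(f"mutant codon at {res} equals the wild codon")
            if _CODON_TABLE[mut.upper()] == _CODON_TABLE[wild.upper()]:
                raise ValueError(
                    f"requested nonsynonymous change at codon {res} "
                    f"({wild}->{mut}) does not alter the amino acid"
                )
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        for res, labels in self.genotype_config.items():
            if len(labels) != self.n_individuals:
                raise ValueError(
                    f"genotype_config at residue {res} covers {len(labels)} of "
                    f"{self.n_individuals} individuals"
                )
            bad = set(labels) - {"hom_wild", "het", "hom_mutant"}
            if bad:
                raise ValueError(f"unknown zygosity label(s) {sorted(bad)}")

    @property
    def sites(self) -> dict:
        """residue -> (wild codon, mutant codon) for the nonsynonymous sites."""
        return {res: (wild.upper(), mut.upper()) for res, wild, mut in self.nonsyn_changes}


def generate_strain_pair(spec: SequenceSimSpec):
    """(susceptible, resistant) CDS pair with the planted differences.

    The resistant CDS differs from the susceptible one at exactly
    len(syn_positions) single synonymous bases plus the per-codon base
    differences of the nonsynonymous changes; the translations differ only at
    the nonsynonymous codons.
    """
    rng = np.random.default_rng(spec.seed)
    sus = spec.template_cds
    res = list(sus)
    for residue in spec.syn_positions:
        idx = residue - spec.offset - 1
        codon = sus[idx * 3 : idx * 3 + 3]
        res[idx * 3 : idx * 3 + 3] = synonymous_substitution(codon, rng)
    for residue, _, mut in spec.nonsyn_changes:
        idx = residue - spec.offset - 1
        res[idx * 3 : idx * 3 + 3] = mut.upper()
    return (
        CodingSequence(id="susceptible", seq=sus, offset=spec.offset),
        CodingSequence(id="resistant", seq="".join(res), offset=spec.offset),
    )


@dataclass(frozen=True)
class GenotypePanel:
    """Per-individual consensus amplicons with the planted truth retained."""

    individuals: dict  # id -> amplicon sequence (IUPAC consensus)
    sites: dict  # residue -> (wild codon, mutant codon)
    truth: dict  # residue -> tuple of zygosity labels, one per individual
    offset: int = 0


def _het_codon(wild: str, mut: str) -> str:
    out = []
    for a, b in zip(wild, mut):
        out.append(a if a == b else IUPAC_FROM_BASES[frozenset((a, b))])
    return "".join(out)


def generate_genotype_panel(spec: SequenceSimSpec) -> GenotypePanel:
    """Diploid amplicon panel: heterozygous sites carry IUPAC ambiguity codes.

    Homozygous individuals carry the plain wild or mutant codon; heterozygotes
    carry the two-base IUPAC code at each differing base (Sanger-style
    consensus).
    """
    sites = spec.sites
    for res in spec.genotype_config:
        if res not in sites:
            raise ValueError(f"genotype_config residue {res} has no planted mutation")
    individuals = {}
    for i in range(spec.n_individuals):
        seq = list(spec.template_cds)
        for res, labels in spec.genotype_config.items():
            wild, mut = sites[res]
            label = labels[i]
            codon = {"hom_wild": wild, "hom_mutant": mut, "het": _het_codon(wild, mut)}[label]
            idx = res - spec.offset - 1
            seq[idx * 3 : idx * 3 + 3] = codon
        individuals[f"ind{i + 1:02d}"] = "".join(seq)
    return GenotypePanel(
        individuals=individuals,
        sites=sites,
        truth={res: tuple(labels) for res, labels in spec.genotype_config.items()},
        offset=spec.offset,
    )
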