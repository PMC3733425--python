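"""Ion and denaturing-agent corrections.

All nearest-neighbor parameter sets used here are referenced to 1 M sodium.
Computing a melting temperature in a different buffer therefore needs a
correction, applied one of two ways:

* *entropy-type* corrections modify the sodium-dependent part of the duplex
  entropy before the Tm formula (the salt-independent entropy of large
  internal loops is never touched);
* *temperature-type* corrections transform the Tm computed at the 1 M
  reference.

Mixed buffers (K+, Tris, Mg2+) are first mapped onto an equivalent sodium
concentration by a registered sodium-equivalence method, and the
appropriate correction class (sodium / magnesium / mixed
monovalent-bivalent) is selected by the cation-competition algorithm of
Owczarzy et al. (2008): with R = sqrt([Mg2+]_free) / [monovalent], a
sodium correction applies for R < 0.22, the magnesium correction for
R >= 6 (or no monovalent ions), and the mixed correction in between.

Denaturing agents (DMSO as volume percent, formamide) shift the final Tm
by affine rules applied after — and independently of — the ion step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from . import config
from .errors import (NotApplicableError, UnknownMethodError, ValidationError)

ALL_HYBRIDIZATIONS = ("dnadna", "rnarna", "dnarna", "rnadna", "mrnarna")
KELVIN = 273.15


@dataclass
class Environment:
    """The chemical environment of the hybridization.

    Concentrations are mol/L; DMSO is a volume percentage; formamide is
    interpreted by the chosen correction (mol/L for the default
    GC-dependent rule, percent for the linear rule).  ``CT`` is the total
    oligomer concentration; ``Cmax``/``Cmin`` optionally give the two
    strand concentrations.  F is the nucleic-acid correction factor of the
    Tm formula (1 or 4).
    """

    hybridization: str = "dnadna"
    Na: float = 0.0
    K: float = 0.0
    Tris: float = 0.0
    Mg: float = 0.0
    dNTP: float = 0.0
    DMSO: float = 0.0        # percent v/v
    formamide: float = 0.0
    CT: float = 0.0
    Cmax: float | None = None
    Cmin: float | None = None
    self_complementary: bool = False
    strand_excess: bool = False

    def __post_init__(self):
        for name in ("Na", "K", "Tris", "Mg", "dNTP", "DMSO", "formamide", "CT"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} concentration must be >= 0")
        if (self.Cmax is None) != (self.Cmin is None):
            raise ValidationError("Cmax and Cmin must be given together")
        if self.Cmax is not None and (self.Cmax <= 0 or self.Cmin <= 0):
            raise ValidationError("strand concentrations must be > 0")

    @property
    def monovalent(self) -> float:
        """Monovalent cation concentration seen by the selector:
        Na+ + K+ + Tris/2 (half the Tris buffer is protonated)."""
        return self.Na + self.K + self.Tris / 2.0

    @property
    def free_magnesium(self) -> float:
        """Magnesium not chelated by dNTPs, clamped at zero."""
        return max(self.Mg - self.dNTP, 0.0)

    def has_cation(self) -> bool:
        return (self.Na > 0 or self.K > 0 or self.Tris > 0 or self.Mg > 0)

    def require_cation(self) -> None:
        if not self.has_cation():
            raise ValidationError(
                "at least one cation concentration (Na, K, Tris or Mg) "
                "is required")


# ---------------------------------------------------------------------------
# sodium equivalence

def _naeq_ahs01(env: Environment) -> float:
    # von Ahsen et al. 2001: monovalents plus 3.79 sqrt(free Mg) (the
    # 120*sqrt(mM) rule expressed in mol/L), dNTPs chelating magnesium.
    return env.monovalent + 3.79 * math.sqrt(env.free_magnesium)


def _naeq_mit96(env: Environment) -> float:
    # Mitsuhashi 1996: same monovalent sum and magnesium factor, without
    # the dNTP chelation term.
    return env.monovalent + 3.79 * math.sqrt(env.Mg)


def _naeq_pey00(env: Environment) -> float:
    # Peyret 2000: smaller magnesium weighting.
    return env.monovalent + 3.3 * math.sqrt(env.free_magnesium)


NAEQ_METHODS: dict[str, Callable[[Environment], float]] = {
    "ahs01": _naeq_ahs01,
    "mit96": _naeq_mit96,
    "pey00": _naeq_pey00,
}


def sodium_equivalent(env: Environment, method: str | None = None) -> float:
    """Equivalent sodium concentration (mol/L) of a mixed-cation buffer."""
    method = method or config.get("default_naeq")
    try:
        fn = NAEQ_METHODS[method]
    except KeyError:
        raise UnknownMethodError(
            f"unknown sodium-equivalence method {method!r}; "
            f"registered: {', '.join(sorted(NAEQ_METHODS))}") from None
    return fn(env)


# ---------------------------------------------------------------------------
# ion corrections

@dataclass(frozen=True)
class CorrectionContext:
    """Inputs an ion correction may consult."""

    na_eq: float
    monovalent: float
    mg_free: float
    fgc: float       # GC fraction of paired columns, in [0, 1]
    n_bp: int        # paired column count
    mixed: bool = False


@dataclass(frozen=True)
class IonCorrection:
    """Registry entry: formula plus the metadata the engine enforces."""

    id: str
    kind: str                        # "entropy" | "temperature"
    scope: tuple[str, ...]
    citation: str
    func: Callable
    reference_naeq: float | None = 1.0   # NaEq fixed point; None for Mg type
    ion_class: str = "sodium"            # "sodium" | "magnesium" | "mixed"

    def check_scope(self, hybridization: str) -> None:
        if hybridization not in self.scope:
            raise NotApplicableError(
                f"ion correction {self.id!r} applies to "
                f"{', '.join(self.scope)} duplexes, not {hybridization!r}")


def _tm_schlif(tm: float, ctx: CorrectionContext) -> float:
    return tm + 16.6 * math.log10(ctx.na_eq)


def _tm_wet91(tm: float, ctx: CorrectionContext) -> float:
    # Wetmur 1991 relative form; identity at the 1 M reference.
    return tm + 16.6 * math.log10(1.7 * ctx.na_eq / (1.0 + 0.7 * ctx.na_eq))


def _tm_san96(tm: float, ctx: CorrectionContext) -> float:
    return tm + 12.5 * math.log10(ctx.na_eq)


def _tm_kam71(tm: float, ctx: CorrectionContext) -> float:
    # Frank-Kamenetskii 1971: GC-dependent slope on ln[Na+].
    return tm + (7.95 - 3.06 * ctx.fgc) * math.log(ctx.na_eq)


def _tm_owc2104(tm: float, ctx: CorrectionContext) -> float:
    inv = 1.0 / (tm + KELVIN) + (4.29 * ctx.fgc - 3.95) * 1e-5 * math.log(ctx.na_eq)
    return 1.0 / inv - KELVIN


def _tm_owc2204(tm: float, ctx: CorrectionContext) -> float:
    ln = math.log(ctx.na_eq)
    inv = (1.0 / (tm + KELVIN)
           + (4.29 * ctx.fgc - 3.95) * 1e-5 * ln
           + 9.40e-6 * ln * ln)
    return 1.0 / inv - KELVIN


def _ds_san04(ds_salt_dependent: float, ctx: CorrectionContext) -> float:
    # Per-phosphate-pair entropy shift: 0.368 (N_bp - 1) ln[Na+].
    return ds_salt_dependent + 0.368 * (ctx.n_bp - 1) * math.log(ctx.na_eq)


def _tm_owcmg08(tm: float, ctx: CorrectionContext) -> float:
    # Owczarzy et al. 2008 magnesium correction on 1/Tm; in the mixed
    # monovalent/bivalent regime three coefficients become functions of
    # the monovalent concentration.
    mg, mon = ctx.mg_free, ctx.monovalent
    if mg <= 0:
        raise NotApplicableError("the magnesium correction needs free Mg2+")
    a, b, c, d = 3.92e-5, -9.11e-6, 6.26e-5, 1.42e-5
    e, f, g = -4.82e-4, 5.25e-4, 8.31e-5
    if ctx.mixed and mon > 0:
        lnm = math.log(mon)
        a *= 0.843 - 0.352 * math.sqrt(mon) * lnm
        d *= 1.279 - 4.03e-3 * lnm - 8.03e-3 * lnm * lnm
        g *= 0.486 - 0.258 * lnm + 5.25e-3 * lnm ** 3
    lnmg = math.log(mg)
    inv = (1.0 / (tm + KELVIN) + a + b * lnmg + ctx.fgc * (c + d * lnmg)
           + (1.0 / (2.0 * (ctx.n_bp - 1))) * (e + f * lnmg + g * lnmg * lnmg))
    return 1.0 / inv - KELVIN


_DNA = ("dnadna",)
_ANY = ALL_HYBRIDIZATIONS

ION_CORRECTIONS: dict[str, IonCorrection] = {c.id: c for c in (
    IonCorrection("schlif", "temperature", _DNA,
                  "Schildkraut & Lifson 1965", _tm_schlif),
    IonCorrection("marschdot", "temperature", _DNA,
                  "Marmur-Schildkraut-Doty", _tm_schlif),
    IonCorrection("ahs01", "temperature", _DNA,
                  "von Ahsen et al. 2001", _tm_schlif),
    IonCorrection("wet91", "temperature", _DNA, "Wetmur 1991 (DNA)", _tm_wet91),
    IonCorrection("wet91rna", "temperature", ("rnarna", "mrnarna"),
                  "Wetmur 1991 (RNA)", _tm_wet91),
    IonCorrection("wet91dnarna", "temperature", ("dnarna", "rnadna"),
                  "Wetmur 1991 (DNA/RNA)", _tm_wet91),
    IonCorrection("san96", "temperature", _DNA, "SantaLucia et al. 1996",
                  _tm_san96),
    IonCorrection("san04", "entropy", _DNA, "SantaLucia & Hicks 2004",
                  _ds_san04),
    IonCorrection("kam71", "temperature", _DNA, "Frank-Kamenetskii 1971",
                  _tm_kam71),
    IonCorrection("owc2104", "temperature", _DNA, "Owczarzy et al. 2004",
                  _tm_owc2104),
    IonCorrection("owc2204", "temperature", _DNA, "Owczarzy et al. 2004",
                  _tm_owc2204),
    IonCorrection("owcmg08", "temperature", _DNA, "Owczarzy et al. 2008",
                  _tm_owcmg08, reference_naeq=None, ion_class="magnesium"),
)}


def select_ion_correction(env: Environment,
                          forced: str | None = None) -> IonCorrection:
    """Pick the ion correction for an environment.

    A forced id wins unconditionally (scope is still enforced at apply
    time).  Otherwise the Owczarzy 2008 competition ratio decides between
    the sodium-class default for the hybridization, the magnesium
    correction and the mixed monovalent/bivalent correction.
    """
    if forced is not None:
        try:
            return ION_CORRECTIONS[forced]
        except KeyError:
            raise UnknownMethodError(
                f"unknown ion correction {forced!r}; registered: "
                f"{', '.join(sorted(ION_CORRECTIONS))}") from None
    env.require_cation()
    mg = env.free_magnesium
    mon = env.monovalent
    sodium_default = config.get("default_sodium_correction")[env.hybridization]
    if mg <= 0:
        return ION_CORRECTIONS[sodium_default]
    if mon <= 0:
        return ION_CORRECTIONS[config.get("default_magnesium_correction")]
    ratio = math.sqrt(mg) / mon
    if ratio < config.get("owczarzy_ratio_low"):
        return ION_CORRECTIONS[sodium_default]
    if ratio < config.get("owczarzy_ratio_high"):
        return ION_CORRECTIONS[config.get("default_mixed_correction")]
    return ION_CORRECTIONS[config.get("default_magnesium_correction")]


def is_mixed_regime(env: Environment) -> bool:
    """True when monovalent and bivalent cations compete (the intermediate
    band of the Owczarzy 2008 ratio)."""
    mg, mon = env.free_magnesium, env.monovalent
    if mg <= 0 or mon <= 0:
        return False
    ratio = math.sqrt(mg) / mon
    return config.get("owczarzy_ratio_low") <= ratio < config.get("owczarzy_ratio_high")


def correction_context(env: Environment, fgc: float, n_bp: int,
                       naeq_method: str | None = None,
                       mixed: bool = False) -> CorrectionContext:
    return CorrectionContext(na_eq=sodium_equivalent(env, naeq_method),
                             monovalent=env.monovalent,
                             mg_free=env.free_magnesium,
                             fgc=fgc, n_bp=n_bp, mixed=mixed)


def apply_ion_correction(value: float, env: Environment,
                         correction: IonCorrection | str,
                         ctx: CorrectionContext) -> float:
    """Apply one registered correction.

    ``value`` is the sodium-dependent entropy (cal/(mol.K)) for
    entropy-type corrections and the Tm at the 1 M reference (deg C) for
    temperature-type ones; the corrected quantity is returned.
    """
    if isinstance(correction, str):
        try:
            correction = ION_CORRECTIONS[correction]
        except KeyError:
            raise UnknownMethodError(
                f"unknown ion correction {correction!r}") from None
    correction.check_scope(env.hybridization)
    if correction.ion_class == "sodium" and ctx.na_eq <= 0:
        raise ValidationError("a sodium-class correction needs a positive "
                              "sodium-equivalent concentration")
    return correction.func(value, ctx)


# ---------------------------------------------------------------------------
# denaturing agents

def _dmso_linear(factor: float):
    def fn(tm: float, env: Environment, fgc: float) -> float:
        return tm - factor * env.DMSO
    return fn


def _formamide_bla96(tm: float, env: Environment, fgc: float) -> float:
    # Blake & Delcourt 1996: GC-dependent shift per mol/L formamide.
    return tm + (0.453 * fgc - 2.88) * env.formamide


def _formamide_linear(tm: float, env: Environment, fgc: float) -> float:
    # Classic linear rule: -0.62 deg C per volume percent formamide.
    return tm - 0.62 * env.formamide


DMSO_CORRECTIONS = {
    "ahs01dmso": _dmso_linear(0.75),   # von Ahsen et al. 2001
    "mus81": _dmso_linear(0.6),        # Musielski et al. 1981
    "cul76": _dmso_linear(0.5),        # Cullen & Bick 1976
    "esc80": _dmso_linear(0.675),      # Escara & Hutton 1980
}

FORMAMIDE_CORRECTIONS = {
    "bla96": _formamide_bla96,
    "lincorr": _formamide_linear,
}


def denaturant_correction(tm: float, env: Environment, agent: str,
                          method: str | None = None, fgc: float = 0.5) -> float:
    """Corrected Tm after one denaturing agent; identity at zero dose."""
    if agent == "DMSO":
        registry, dose = DMSO_CORRECTIONS, env.DMSO
        method = method or config.get("default_dmso_correction")
    elif agent == "formamide":
        registry, dose = FORMAMIDE_CORRECTIONS, env.formamide
        method = method or config.get("default_formamide_correction")
    else:
        raise UnknownMethodError(f"unknown denaturing agent {agent!r}")
    if dose == 0:
        return tm
    try:
        fn = registry[method]
    except KeyError:
        raise UnknownMethodError(
            f"unknown {agent} correction {method!r}; registered: "
            f"{', '.join(sorted(registry))}") from None
    return fn(tm, env, fgc)


# ---------------------------------------------------------------------------
# benchmark harness

def error_margin(tm_computed: float, tm_experimental: float) -> float:
    """Relative prediction error (Tm_computed - Tm_exp) / Tm_exp."""
    if tm_experimental == 0:
        raise ValidationError("experimental Tm must be nonzero")
    return (tm_computed - tm_experimental) / tm_experimental
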