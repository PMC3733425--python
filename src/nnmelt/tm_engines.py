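"""Melting-temperature formulas and the computation pipeline.

Nearest-neighbor path:

    Tm(degC) = dH / (dS + R ln(CT / F)) - 273.15

with R = 1.9872 cal/(mol.K).  F is 1 for self-complementary duplexes; for
non-self-complementary duplexes it is 4 when both strands are equimolar and
1 when one strand is in excess.  When the two strand concentrations are
known the concentration term becomes ln(Cmax - Cmin/2), which tends to
ln(CT) for a large excess and to ln(CT/4) at equimolarity.

Self-complementary duplexes made purely of 5-7 CNG triplet repeats melt
through a dominant hairpin and use the concentration-free form
Tm = dH/dS - 273.15; 2-4 repeats use the duplex formula with F = 1.

Long duplexes (above a configurable length threshold) fall back to
approximative, composition-based formulas (Wetmur 1991 per hybridization),
which embed their own sodium dependence: the engine maps mixed buffers to
an equivalent sodium concentration first and applies no further ion
correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import config, paramstore
from .corrections import (Environment, apply_ion_correction,
                          correction_context, denaturant_correction,
                          is_mixed_regime, select_ion_correction,
                          sodium_equivalent)
from .energetics import (EnergyBreakdown, EnergyModel, compute_breakdown,
                         pre_correct_0p1M_set)
from .errors import (NotApplicableError, ParameterLoadError,
                     UnknownMethodError, ValidationError)
from .segmentation import detect_cng
from .sequences import Duplex

R_GAS = 1.9872        # cal/(mol.K)
KELVIN = 273.15


@dataclass
class MeltingResult:
    """Outcome of one computation.

    ``dh``/``ds`` are None on the approximative path, which predicts the
    temperature directly from composition.  ``diagnostics`` carries the
    verbose payload (alignment, segments, per-segment energies, NaEq,
    chosen formulae).
    """

    tm: float
    method: str                       # "nn" | "approx"
    formula: str
    dh: float | None = None
    ds: float | None = None
    corrections_applied: list[str] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)


def f_factor(env: Environment, excess_ratio: float | None = None) -> int:
    """Nucleic-acid correction factor F of the duplex Tm formula."""
    if env.self_complementary:
        return 1
    if env.strand_excess:
        return 1
    if env.Cmax is not None and env.Cmin is not None:
        ratio = max(env.Cmax, env.Cmin) / min(env.Cmax, env.Cmin)
        if ratio >= config.get("strand_excess_ratio", excess_ratio):
            return 1
    return 4


def _concentration_term(env: Environment) -> float:
    """The argument of the ln() concentration term of the Tm formula."""
    if env.CT <= 0:
        raise ValidationError("total oligomer concentration CT must be > 0")
    if (not env.self_complementary and env.Cmax is not None
            and env.Cmin is not None):
        cmax, cmin = max(env.Cmax, env.Cmin), min(env.Cmax, env.Cmin)
        return cmax - cmin / 2.0
    return env.CT / f_factor(env)


def tm_nn(breakdown: EnergyBreakdown, env: Environment) -> float:
    """Duplex melting temperature (deg C) at the 1 M sodium reference."""
    total = breakdown.total
    x = _concentration_term(env)
    if x <= 0:
        raise ValidationError("concentration term must be positive")
    denom = total.ds + R_GAS * math.log(x)
    if denom == 0:
        raise ValidationError("degenerate input: dS + R ln(CT/F) is zero")
    return total.dh / denom - KELVIN


def tm_cng(breakdown: EnergyBreakdown, repeats: int,
           env: Environment | None = None) -> float:
    """Melting temperature of a CNG-repeat duplex.

    5-7 repeats melt through the hairpin (concentration-free); 2-4 repeats
    use the duplex formula with F = 1 (CNG sequences are
    self-complementary), which requires ``env``.
    """
    total = breakdown.total
    if 5 <= repeats <= 7:
        if total.ds == 0:
            raise ValidationError("degenerate input: dS is zero")
        return total.dh / total.ds - KELVIN
    if env is None:
        raise ValidationError("2-4 CNG repeats use the duplex formula and "
                              "need the environment")
    return tm_nn(breakdown, env)


def tm_wetmur_dna(gc_percent: float, size: int, na_eq: float,
                  mismatch_percent: float = 0.0) -> float:
    """Wetmur 1991 approximative formula for DNA/DNA duplexes."""
    if size < 1:
        raise ValidationError("duplex size must be >= 1")
    if na_eq <= 0:
        raise ValidationError("sodium-equivalent concentration must be > 0")
    return (81.5 + 16.6 * math.log10(na_eq / (1.0 + 0.7 * na_eq))
            + 0.41 * gc_percent - 500.0 / size - mismatch_percent)


def tm_wetmur_rna(gc_percent: float, size: int, na_eq: float,
                  mismatch_percent: float = 0.0) -> float:
    """Wetmur 1991 approximative formula for RNA/RNA duplexes."""
    if size < 1 or na_eq <= 0:
        raise ValidationError("invalid size or sodium concentration")
    return (78.0 + 16.6 * math.log10(na_eq / (1.0 + 0.7 * na_eq))
            + 0.7 * gc_percent - 500.0 / size - mismatch_percent)


def tm_wetmur_dnarna(gc_percent: float, size: int, na_eq: float,
                     mismatch_percent: float = 0.0) -> float:
    """Wetmur 1991 approximative formula for DNA/RNA hybrids."""
    if size < 1 or na_eq <= 0:
        raise ValidationError("invalid size or sodium concentration")
    return (67.0 + 16.6 * math.log10(na_eq / (1.0 + 0.7 * na_eq))
            + 0.8 * gc_percent - 500.0 / size - mismatch_percent)


APPROX_FORMULAS = {
    "wetdna91": (tm_wetmur_dna, ("dnadna",)),
    "wetrna91": (tm_wetmur_rna, ("rnarna", "mrnarna")),
    "wetdnarna91": (tm_wetmur_dnarna, ("dnarna", "rnadna")),
}


def select_method(duplex: Duplex, env: Environment,
                  threshold: int | None = None,
                  forced: str | None = None) -> str:
    """``"nn"`` or ``"approx"``: forced choice wins, else the length
    threshold on paired columns decides."""
    if forced is not None:
        if forced not in ("nn", "approx"):
            raise UnknownMethodError(
                f"unknown computation method {forced!r}; use 'nn' or 'approx'")
        return forced
    threshold = config.get("nn_length_threshold", threshold)
    return "nn" if len(duplex.paired_columns()) <= threshold else "approx"


def _composition(duplex: Duplex) -> tuple[float, float, int]:
    """(%GC, %mismatching, size) over paired (non-gap) columns."""
    paired = duplex.paired_columns()
    size = len(paired)
    if size == 0:
        raise ValidationError("duplex has no paired columns")
    gc = sum(1 for i in paired
             if duplex.top.tokens[i].symbol in ("G", "C")) / size
    mism = sum(1 for i in paired if not duplex.is_wc_pair(i)) / size
    return 100.0 * gc, 100.0 * mism, size


@dataclass
class Options:
    """Method/parameter overrides of one computation (all optional)."""

    threshold: int | None = None
    force_method: str | None = None       # "nn" | "approx"
    parameter_set: str | None = None      # default NN set id
    nn_overrides: dict[str, str] = field(default_factory=dict)  # kind -> set id
    approx_id: str | None = None
    ion_id: str | None = None
    naeq_id: str | None = None
    dmso_id: str | None = None
    formamide_id: str | None = None
    data_dir: str | None = None
    polya_min: int | None = None


def _build_model(duplex: Duplex, options: Options) -> EnergyModel:
    registry = paramstore.default_registry(options.data_dir)
    set_id = options.parameter_set
    if set_id is None:
        set_id = config.get("default_parameter_sets").get(duplex.hybridization)
    if set_id is None:
        raise ParameterLoadError(
            f"no default parameter set ships for {duplex.hybridization!r} "
            "duplexes; supply one with --nn or --data")
    default_set = pre_correct_0p1M_set(registry.get(set_id))
    per_kind = {kind: pre_correct_0p1M_set(registry.get(sid))
                for kind, sid in options.nn_overrides.items()}
    return EnergyModel(default_set, per_kind)


def _compute_nn(duplex: Duplex, env: Environment, options: Options,
                diagnostics: dict) -> MeltingResult:
    model = _build_model(duplex, options)
    segments, breakdown = compute_breakdown(duplex, model,
                                            polya_min=options.polya_min)
    fgc, _, n_bp = _composition(duplex)
    corrections_applied: list[str] = []
    cng = detect_cng(duplex)

    correction = select_ion_correction(env, options.ion_id)
    correction.check_scope(env.hybridization)
    ctx = correction_context(env, fgc / 100.0, n_bp, options.naeq_id,
                             mixed=is_mixed_regime(env))
    if correction.kind == "entropy":
        ds_dep = apply_ion_correction(breakdown.ds_salt_dependent, env,
                                      correction, ctx)
        shift = ds_dep - breakdown.ds_salt_dependent
        breakdown = EnergyBreakdown(
            per_segment=breakdown.per_segment,
            initiation=breakdown.initiation,
            symmetry=breakdown.symmetry + paramstore.ThermoResult(0.0, shift),
            ds_salt_independent=breakdown.ds_salt_independent)
        tm = tm_cng(breakdown, cng, env) if cng else tm_nn(breakdown, env)
    else:
        tm = tm_cng(breakdown, cng, env) if cng else tm_nn(breakdown, env)
        tm = apply_ion_correction(tm, env, correction, ctx)
    corrections_applied.append(correction.id)

    if env.DMSO > 0:
        tm = denaturant_correction(tm, env, "DMSO", options.dmso_id,
                                   fgc=fgc / 100.0)
        corrections_applied.append(options.dmso_id
                                   or config.get("default_dmso_correction"))
    if env.formamide > 0:
        tm = denaturant_correction(tm, env, "formamide", options.formamide_id,
                                   fgc=fgc / 100.0)
        corrections_applied.append(options.formamide_id
                                   or config.get("default_formamide_correction"))

    total = breakdown.total
    diagnostics.update(
        segments=segments,
        per_segment_energies=[(s.kind, t.dh, t.ds)
                              for s, t in breakdown.per_segment],
        initiation=(breakdown.initiation.dh, breakdown.initiation.ds),
        symmetry=(breakdown.symmetry.dh, breakdown.symmetry.ds),
        ds_salt_independent=breakdown.ds_salt_independent,
        parameter_set=model.default_set.id,
        na_eq=ctx.na_eq,
        f_factor=f_factor(env),
    )
    return MeltingResult(tm=tm, method="nn", formula=model.default_set.id,
                         dh=total.dh, ds=total.ds,
                         corrections_applied=corrections_applied,
                         diagnostics=diagnostics)


def _compute_approx(duplex: Duplex, env: Environment, options: Options,
                    diagnostics: dict) -> MeltingResult:
    env.require_cation()
    approx_id = options.approx_id
    if approx_id is None:
        approx_id = config.get("default_approx")[env.hybridization]
    try:
        fn, scope = APPROX_FORMULAS[approx_id]
    except KeyError:
        raise UnknownMethodError(
            f"unknown approximative formula {approx_id!r}; registered: "
            f"{', '.join(sorted(APPROX_FORMULAS))}") from None
    if env.hybridization not in scope:
        raise NotApplicableError(
            f"approximative formula {approx_id!r} applies to "
            f"{', '.join(scope)} duplexes, not {env.hybridization!r}")
    gc, mism, size = _composition(duplex)
    na_eq = sodium_equivalent(env, options.naeq_id)
    tm = fn(gc, size, na_eq, mism)
    # Approximative formulas embed their sodium dependence: no ion
    # correction is ever stacked on top (denaturants still apply).
    corrections_applied: list[str] = []
    if env.DMSO > 0:
        tm = denaturant_correction(tm, env, "DMSO", options.dmso_id,
                                   fgc=gc / 100.0)
        corrections_applied.append(options.dmso_id
                                   or config.get("default_dmso_correction"))
    if env.formamide > 0:
        tm = denaturant_correction(tm, env, "formamide", options.formamide_id,
                                   fgc=gc / 100.0)
        corrections_applied.append(options.formamide_id
                                   or config.get("default_formamide_correction"))
    diagnostics.update(gc_percent=gc, mismatch_percent=mism, size=size,
                       na_eq=na_eq)
    return MeltingResult(tm=tm, method="approx", formula=approx_id,
                         corrections_applied=corrections_applied,
                         diagnostics=diagnostics)


def compute(duplex: Duplex, env: Environment,
            options: Options | None = None) -> MeltingResult:
    """Full pipeline: method selection, energetics or composition, then
    corrections in the order ion -> denaturants."""
    options = options or Options()
    env.require_cation()
    if env.self_complementary != duplex.self_complementary:
        env = Environment(**{**env.__dict__,
                             "self_complementary": duplex.self_complementary
                             or env.self_complementary})
    diagnostics = {
        "alignment": (duplex.top.text, duplex.bottom.text),
        "hybridization": duplex.hybridization,
    }
    method = select_method(duplex, env, options.threshold, options.force_method)
    if method == "nn":
        return _compute_nn(duplex, env, options, diagnostics)
    return _compute_approx(duplex, env, options, diagnostics)
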