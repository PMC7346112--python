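"""Internal-reference quantification of 1H NMR spectra of oxidising oils.

The concentration of a functional group X follows from the area A_X of its
selected signal, the number n of protons generating it, and the area A_TG of
the triglyceride glyceryl sn-1/sn-3 protons (4 per TG), used as internal
reference because triglycerides undergo negligible hydrolysis during
oxidation::

    [X] = (A_X / n) / (A_TG / 4) * 1000        (mmol / mol TG)

Overlapping windows are handled by area bookkeeping, not lineshape fitting:
before Eq. (1) is applied to a window, the predicted in-window contribution of
every catalogued co-resonant peak (its compound's already-measured
concentration x its proton count x its analytic Lorentzian mass fraction
inside the window, re-expressed in area units through A_TG/4) is subtracted,
in the topological order of the catalogue's corrections DAG.  Each integrated
area is also divided by the analytic in-window fraction of its own Lorentzian,
so heterogeneous window widths do not bias the concentration ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._lorentz import window_fraction
from .catalogue import Catalogue, CatalogueError, SignalAssignment
from .synth import Spectrum

__all__ = [
    "WindowArea",
    "QuantResult",
    "integrate_window",
    "eq1_concentration",
    "apply_corrections",
    "quantify_spectrum",
    "average_replicates",
]

DEFAULT_LOD = 0.5  # mmol/mol TG
DEFAULT_OOH_SWITCH_DAY = 9.0  # wide 8.3-9.3 ppm OOH window from this day onward
A_TG_FLOOR = 1e-9


@dataclass
class WindowArea:
    """Raw and corrected integral of one quantification window."""

    signal_id: str
    window: tuple[float, float]
    area: float
    corrected_area: float | None = None
    clamped: bool = False


@dataclass
class QuantResult:
    """Concentrations (mmol/mol TG) of one spectrum, with bookkeeping."""

    concentrations: dict[str, float]
    a_tg: float
    lod: float
    flags: dict[str, set[str]] = field(default_factory=dict)
    window_areas: dict[str, WindowArea] = field(default_factory=dict)

    def reported(self, compound_id: str) -> float:
        """Concentration with below-LOD values reported as 0."""
        c = self.concentrations.get(compound_id, 0.0)
        return c if c >= self.lod else 0.0


def integrate_window(s: Spectrum, window: tuple[float, float]) -> float:
    """Trapezoidal integral of intensity over a ppm window, intensity*ppm.

    Uses the native grid points inside the window plus intensity values
    interpolated at the exact window bounds.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"empty window [{lo}, {hi}]")
    ppm, y = s.ppm, s.intensity
    if s.descending:
        ppm, y = ppm[::-1], y[::-1]
    if lo < ppm[0] or hi > ppm[-1]:
        raise ValueError(f"window [{lo}, {hi}] outside spectrum range "
                         f"[{ppm[0]:g}, {ppm[-1]:g}]")
    i0, i1 = np.searchsorted(ppm, lo, "left"), np.searchsorted(ppm, hi, "right")
    xs = np.concatenate(([lo], ppm[i0:i1], [hi]))
    ys = np.concatenate(([np.interp(lo, ppm, y)], y[i0:i1], [np.interp(hi, ppm, y)]))
    keep = np.concatenate(([True], np.diff(xs) > 0))
    return float(np.trapezoid(ys[keep], xs[keep]))


def eq1_concentration(a_x: float, n: int, a_tg: float) -> float:
    """Internal-reference concentration formula, mmol/mol TG."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if a_tg <= 0:
        raise ValueError("reference area A_TG must be > 0")
    return (a_x / n) / (a_tg / 4.0) * 1000.0


# ---------------------------------------------------------------------------
# correction bookkeeping
# ---------------------------------------------------------------------------

def _window_signals(cat: Catalogue) -> list[SignalAssignment]:
    """Reference sub-windows and non-aggregate quantifier windows.

    Aggregate channels (functional-group totals) are integrated last, once
    the concentrations of their constituents are known (see
    :func:`quantify_spectrum`)."""
    out = []
    for sid in sorted(cat.signals):
        s = cat.signals[sid]
        if s.role not in ("reference", "quantifier"):
            continue
        if cat.compounds[s.compound_id].aggregate:
            continue
        out.append(s)
    return out


def _augmented_order(cat: Catalogue, sids: Iterable[str]) -> list[str]:
    """Topological order where every correction's contributor *compound*
    (via its quantifier signal) precedes the corrected window."""
    sids = set(sids)

    def deps(sid: str) -> list[str]:
        out = []
        for j in cat.signals[sid].corrections:
            q = cat.quantifier_of(cat.signals[j].compound_id)
            if q is not None and q.signal_id in sids and q.signal_id != sid:
                out.append(q.signal_id)
        return out

    order: list[str] = []
    state: dict[str, int] = {}

    def visit(sid: str, stack: tuple[str, ...]) -> None:
        if state.get(sid) == 2:
            return
        if state.get(sid) == 1:
            raise CatalogueError("correction cycle at compound level: " + " -> ".join(stack + (sid,)))
        state[sid] = 1
        for d in deps(sid):
            visit(d, stack + (sid,))
        state[sid] = 2
        order.append(sid)

    for sid in sorted(sids):
        visit(sid, ())
    return order


def apply_corrections(
    areas: Mapping[str, WindowArea],
    cat: Catalogue,
    *,
    a_tg: float,
    fwhm: float,
) -> tuple[dict[str, WindowArea], dict[str, float]]:
    """Run the overlap-subtraction chain over integrated windows.

    ``areas`` maps signal ids to raw :class:`WindowArea`; the reference
    sub-windows may be included (their corrected areas feed A_TG but they
    yield no concentration).  Returns corrected areas and the per-compound
    concentrations implied by ``a_tg``.

    Raises ``KeyError`` if a correction names a contributor whose area (i.e.
    whose compound's quantifier window) was not supplied.
    """
    out: dict[str, WindowArea] = {}
    # the internal reference is, by definition, 1 mol TG per mol TG; seeding
    # it lets reference tail leakage be subtracted like any other contributor
    concs: dict[str, float] = {cat.reference_compound.id: 1000.0}
    for sid in _augmented_order(cat, areas.keys()):
        sig = cat.signals[sid]
        wa = areas[sid]
        lo, hi = wa.window
        sub = 0.0
        for j in sig.corrections:
            src = cat.signals[j]
            if src.compound_id not in concs:
                raise KeyError(f"{sid}: contributor compound {src.compound_id} not yet quantified")
            leak = window_fraction(src.center, lo, hi, fwhm)
            sub += concs[src.compound_id] * src.n_protons * leak * (a_tg / 4.0) / 1000.0
        corrected = wa.area - sub
        clamped = corrected < 0
        if clamped:
            corrected = 0.0
        out[sid] = replace(wa, corrected_area=corrected, clamped=clamped)
        if sig.role == "quantifier" and not cat.compounds[sig.compound_id].aggregate:
            own = window_fraction(sig.center, lo, hi, fwhm)
            concs[sig.compound_id] = eq1_concentration(corrected / own, sig.n_protons, a_tg)
    return out, concs


# ---------------------------------------------------------------------------
# full-spectrum quantification
# ---------------------------------------------------------------------------

def quantify_spectrum(
    s: Spectrum,
    cat: Catalogue,
    lod: float = DEFAULT_LOD,
    *,
    fwhm: float | None = None,
    day: float | None = None,
    ooh_switch_day: float = DEFAULT_OOH_SWITCH_DAY,
) -> QuantResult:
    """Quantify every catalogued compound class in one spectrum.

    A_TG is summed over the reference sub-windows (each divided by its own
    in-window Lorentzian fraction, corrected for catalogued interlopers);
    every quantifier window is integrated, corrected and converted by the
    internal-reference formula.  Functional-group totals (aggregate
    compounds) are quantified from their collective window: the total
    hydroperoxy channel uses its narrow window before ``ooh_switch_day`` and
    the wide one from that day onward.  Concentrations below ``lod`` are
    reported as 0 and flagged.

    ``fwhm`` and ``day`` default to the spectrum's metadata.
    """
    fwhm = float(fwhm if fwhm is not None else s.meta.get("fwhm", 0.002))
    day = day if day is not None else s.meta.get("day")

    raw: dict[str, WindowArea] = {}
    for sig in _window_signals(cat):
        raw[sig.signal_id] = WindowArea(sig.signal_id, sig.window, integrate_window(s, sig.window))

    ref_sids = [r.signal_id for r in cat.reference_signals]

    def ref_area(areas: Mapping[str, WindowArea], corrected: bool) -> float:
        tot = 0.0
        for sid in ref_sids:
            sig = cat.signals[sid]
            wa = areas[sid]
            a = wa.corrected_area if corrected else wa.area
            tot += a / window_fraction(sig.center, *wa.window, fwhm)
        return tot

    a_tg = ref_area(raw, corrected=False)
    if a_tg <= A_TG_FLOOR:
        raise ValueError("reference lost: A_TG at or below the configured floor")

    # pass 1 with the raw reference, pass 2 with the interloper-corrected one
    areas, concs = apply_corrections(raw, cat, a_tg=a_tg, fwhm=fwhm)
    a_tg = ref_area(areas, corrected=True)
    if a_tg <= A_TG_FLOOR:
        raise ValueError("reference lost: A_TG at or below the configured floor")
    areas, concs = apply_corrections(raw, cat, a_tg=a_tg, fwhm=fwhm)

    # aggregate channels, e.g. the total hydroperoxy-group window: integrate
    # the window in force today, subtract catalogued non-OOH interlopers using
    # the concentrations just measured, and convert with the channel's n
    for cid in sorted(cat.compounds):
        comp = cat.compounds[cid]
        if not comp.aggregate:
            continue
        quant = cat.quantifier_of(cid)
        if quant is None:
            continue
        row = _aggregate_row(cat, cid, day, ooh_switch_day)
        area = integrate_window(s, row.window)
        sub = 0.0
        for j in quant.corrections:
            src = cat.signals[j]
            leak = window_fraction(src.center, *row.window, fwhm)
            sub += concs.get(src.compound_id, 0.0) * src.n_protons * leak * (a_tg / 4.0) / 1000.0
        corrected = max(area - sub, 0.0)
        own = window_fraction(row.center, *row.window, fwhm)
        concs[cid] = eq1_concentration(corrected / own, quant.n_protons, a_tg)
        areas[quant.signal_id] = WindowArea(
            quant.signal_id, row.window, area, corrected, clamped=area - sub < 0
        )

    flags: dict[str, set[str]] = {}
    final: dict[str, float] = {}
    for cid in sorted(cat.compounds):
        q = cat.quantifier_of(cid)
        if q is None or cid not in concs:
            continue
        c = concs[cid]
        f: set[str] = set()
        if q.assumed:
            f.add("assumed_n")
        if areas[q.signal_id].clamped:
            f.add("clamped")
        if c < lod:
            f.add("below_lod")
            c_rep = 0.0
        else:
            c_rep = c
        final[cid] = c_rep
        flags[cid] = f
    return QuantResult(concentrations=final, a_tg=a_tg, lod=lod, flags=flags, window_areas=areas)


def _aggregate_row(
    cat: Catalogue, compound_id: str, day: float | None, switch_day: float
) -> SignalAssignment:
    """Catalogue row carrying an aggregate channel's window today: the OOH
    total uses its narrow early-stage qualifier row before ``switch_day`` and
    the wide quantifier window from that day onward."""
    quant = cat.quantifier_of(compound_id)
    assert quant is not None
    alts = [s for s in cat.signals_of(compound_id) if s.role == "qualifier"]
    if alts and day is not None and day < switch_day:
        return alts[0]
    return quant


def average_replicates(results: Sequence[QuantResult]) -> QuantResult:
    """Arithmetic per-compound mean of replicate determinations; flags are
    OR-combined; LOD semantics re-applied to the mean."""
    if not results:
        raise ValueError("need at least one result")
    if len(results) == 1:
        return results[0]
    cids = sorted({cid for r in results for cid in r.concentrations})
    lod = results[0].lod
    concs: dict[str, float] = {}
    flags: dict[str, set[str]] = {}
    for cid in cids:
        vals = [r.concentrations.get(cid, 0.0) for r in results]
        m = float(np.mean(vals))
        f: set[str] = set()
        for r in results:
            f |= r.flags.get(cid, set())
        if m < lod:
            m = 0.0
            f.add("below_lod")
        else:
            f.discard("below_lod")
        concs[cid] = m
        flags[cid] = f
    a_tg = float(np.mean([r.a_tg for r in results]))
    return QuantResult(concentrations=concs, a_tg=a_tg, lod=lod, flags=flags)
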