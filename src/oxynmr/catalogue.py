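"""Machine-readable 1H NMR signal-assignment catalogue for oxidising omega-6 oils.

The catalogue maps each quantifiable compound class (intact acyl groups, minor
components, primary/secondary oxidation products, small molecules, sterol
oxides) to the spectral signals it generates: chemical-shift center,
integration window, proton count *n*, and the ordered overlap-subtraction
dependencies ("corrections") that must be applied before the internal-reference
concentration formula.

Conventions
-----------
* ppm windows are closed intervals [lo, hi]; the spectral axis itself is
  stored high-to-low (NMR convention) but windows are given lo < hi.
* Exactly one compound is the internal reference: the triglyceride glyceryl
  sn-1/sn-3 CH2 protons (4 per TG).  It is modelled as two sub-window signals
  (4.10-4.18 and 4.26-4.34 ppm) whose summed area is A_TG.
* ``corrections`` form a DAG over signal ids: an entry ``j`` in signal ``i``'s
  list means "subtract the predicted contribution of peak j from window i".
* Aggregate compounds (currently the total hydroperoxy-group channel) are
  quantified from a window that deliberately collects the OOH peaks of several
  compounds; they are never rendered and are exempt from the collision audit.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from ._lorentz import window_fraction

__all__ = [
    "CATEGORIES",
    "ROLES",
    "CatalogueError",
    "CompoundClass",
    "SignalAssignment",
    "Catalogue",
    "load_catalogue",
    "save_catalogue",
    "default_catalogue",
    "audit_collisions",
    "suggest_correction_edges",
]

CATEGORIES = (
    "acyl",
    "minor_component",
    "primary_oxidation",
    "secondary_oxidation",
    "small_molecule",
    "sterol_oxide",
)

ROLES = ("quantifier", "reference", "qualifier")


class CatalogueError(ValueError):
    """Raised when a catalogue fails validation."""


@dataclass(frozen=True)
class CompoundClass:
    """One quantifiable class of compounds (or functional-group total)."""

    id: str
    name: str
    category: str
    first_detected_day: float | None = None
    aggregate: bool = False  # quantified from a collective window, never rendered
    notes: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise CatalogueError(f"{self.id}: unknown category {self.category!r}")
        if self.first_detected_day is not None and not (0 <= self.first_detected_day <= 16):
            raise CatalogueError(f"{self.id}: first_detected_day outside [0, 16]")


@dataclass(frozen=True)
class SignalAssignment:
    """One integrable 1H NMR signal.

    ``n_protons`` is the *n* of the internal-reference formula: protons per
    molecule of the owning compound that resonate under this signal.
    ``corrections`` lists contributor signal ids whose predicted in-window
    area is subtracted before quantification, in order.
    """

    signal_id: str
    compound_id: str
    center: float
    window: tuple[float, float]
    n_protons: int
    multiplicity: str = "m"
    role: str = "quantifier"
    corrections: tuple[str, ...] = ()
    assumed: bool = False  # shift/window/n reconstructed, not printed in a source table
    aggregate_member_of: str = ""  # aggregate compound whose window is meant to collect this peak
    notes: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not lo < hi:
            raise CatalogueError(f"{self.signal_id}: window lo must be < hi")
        if not (lo <= self.center <= hi):
            raise CatalogueError(f"{self.signal_id}: center outside window")
        if not (0 < self.n_protons <= 6):
            raise CatalogueError(f"{self.signal_id}: n_protons must be in (0, 6]")
        if self.role not in ROLES:
            raise CatalogueError(f"{self.signal_id}: unknown role {self.role!r}")


def _overlap(w1: tuple[float, float], w2: tuple[float, float]) -> bool:
    return w1[0] <= w2[1] and w2[0] <= w1[1]


@dataclass
class Catalogue:
    """Validated set of compound classes and their signal assignments."""

    compounds: dict[str, CompoundClass]
    signals: dict[str, SignalAssignment]
    field_mhz: float = 400.0

    # -- lookups ---------------------------------------------------------
    @property
    def reference_compound(self) -> CompoundClass:
        (cid,) = {s.compound_id for s in self.signals.values() if s.role == "reference"}
        return self.compounds[cid]

    @property
    def reference_signals(self) -> list[SignalAssignment]:
        refs = [s for s in self.signals.values() if s.role == "reference"]
        return sorted(refs, key=lambda s: s.signal_id)

    @property
    def reference_n_protons(self) -> int:
        return sum(s.n_protons for s in self.reference_signals)

    def signals_of(self, compound_id: str) -> list[SignalAssignment]:
        out = [s for s in self.signals.values() if s.compound_id == compound_id]
        return sorted(out, key=lambda s: s.signal_id)

    def quantifier_of(self, compound_id: str) -> SignalAssignment | None:
        quants = [s for s in self.signals_of(compound_id) if s.role == "quantifier"]
        if not quants:
            return None
        if len(quants) > 1:
            raise CatalogueError(f"{compound_id}: more than one quantifier signal")
        return quants[0]

    def rendered_compounds(self) -> list[str]:
        """Compound ids that contribute peaks to a synthetic spectrum."""
        return sorted(
            cid
            for cid, c in self.compounds.items()
            if not c.aggregate and self.signals_of(cid)
        )

    # -- validation ------------------------------------------------------
    def validate(self) -> "Catalogue":
        if not self.signals:
            raise CatalogueError("catalogue has no signals (no reference signal)")
        for s in self.signals.values():
            if s.compound_id not in self.compounds:
                raise CatalogueError(f"{s.signal_id}: unknown compound {s.compound_id!r}")
            for dep in s.corrections:
                if dep not in self.signals:
                    raise CatalogueError(f"{s.signal_id}: correction {dep!r} not in catalogue")

        ref_compounds = {s.compound_id for s in self.signals.values() if s.role == "reference"}
        if len(ref_compounds) != 1:
            raise CatalogueError(
                f"catalogue must have exactly one reference compound, found {len(ref_compounds)}"
            )
        (ref_cid,) = ref_compounds
        if any(s.role != "reference" for s in self.signals_of(ref_cid)):
            raise CatalogueError(f"reference compound {ref_cid} has non-reference signals")

        self._toposort()  # raises on cycles

        for cid, comp in self.compounds.items():
            if comp.category != "acyl" and cid != ref_cid and not comp.aggregate:
                if not self.signals_of(cid):
                    raise CatalogueError(f"{cid}: non-acyl compound without any signal")
            self.quantifier_of(cid)  # raises if several

        return self

    def _toposort(self) -> list[str]:
        """Topological order of signal ids along correction edges.

        An edge j -> i (j in i.corrections) means j's compound must be
        quantified before window i can be corrected.
        """
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(sid: str, stack: tuple[str, ...]) -> None:
            if state.get(sid) == 2:
                return
            if state.get(sid) == 1:
                cyc = " -> ".join(stack + (sid,))
                raise CatalogueError(f"correction cycle: {cyc}")
            state[sid] = 1
            for dep in self.signals[sid].corrections:
                visit(dep, stack + (sid,))
            state[sid] = 2
            order.append(sid)

        for sid in sorted(self.signals):
            visit(sid, ())
        return order

    def correction_order(self) -> list[str]:
        """Signal ids in an order where every contributor precedes its targets."""
        return self._toposort()


# ---------------------------------------------------------------------------
# collision audit
# ---------------------------------------------------------------------------

def audit_collisions(cat: Catalogue) -> list[tuple[str, str]]:
    """Overlap problems not covered by a corrections edge.

    Reported pairs (sorted lexicographically) are either two overlapping
    quantification windows of different compounds, or a rendered peak whose
    center falls inside a foreign quantification window, with no corrections
    edge in either direction.  Aggregate windows are exempt: they exist to
    collect foreign peaks.
    """
    problems: set[tuple[str, str]] = set()
    sigs = sorted(cat.signals.values(), key=lambda s: s.signal_id)

    def covered(a: SignalAssignment, b: SignalAssignment) -> bool:
        return a.signal_id in b.corrections or b.signal_id in a.corrections

    def is_window(s: SignalAssignment) -> bool:
        if s.role not in ("quantifier", "reference"):
            return False
        return not cat.compounds[s.compound_id].aggregate

    for i, a in enumerate(sigs):
        for b in sigs[i + 1 :]:
            if a.compound_id == b.compound_id or covered(a, b):
                continue
            clash = False
            if is_window(a) and is_window(b) and _overlap(a.window, b.window):
                clash = True
            rendered_a = not cat.compounds[a.compound_id].aggregate
            rendered_b = not cat.compounds[b.compound_id].aggregate
            if is_window(a) and rendered_b and a.window[0] <= b.center <= a.window[1]:
                clash = True
            if is_window(b) and rendered_a and b.window[0] <= a.center <= b.window[1]:
                clash = True
            if clash:
                problems.add((a.signal_id, b.signal_id))
    return sorted(problems)


# ---------------------------------------------------------------------------
# automatic correction-edge suggestion
# ---------------------------------------------------------------------------

def suggest_correction_edges(
    cat: Catalogue,
    conc_series: Mapping[str, Sequence[tuple[float, float]]],
    *,
    fwhm: float = 0.002,
    impact_threshold: float = 0.005,
    floor: float = 0.1,
) -> list[tuple[str, str]]:
    """Edges (contributor_signal, target_signal) whose tail leakage matters.

    For every rendered peak *j* and every quantification window *i* of a
    different compound, the relative contamination is evaluated day by day on
    the supplied concentration trajectories::

        impact(day) = conc_j(day) * n_j * frac(j in W_i)
                      / (conc_i(day) * n_i * frac(i in W_i))

    over days where the target is at least ``floor`` (mmol/mol TG).  Pairs
    whose worst-day impact exceeds ``impact_threshold`` become candidate
    edges; candidates are added greedily by decreasing impact, skipping any
    edge that would close a correction cycle, so the result is always a DAG
    when merged into the existing corrections.

    ``conc_series`` maps compound ids to (day, concentration) anchor lists
    (piecewise-linear between anchors, zero before the first).
    """

    ref_cid = cat.reference_compound.id

    def series_at(cid: str, day: float) -> float:
        comp = cat.compounds[cid]
        if cid == ref_cid:
            return 1000.0  # 1 mol TG per mol TG, by definition
        if comp.aggregate:
            # collective channel: sum its declared member contributions
            return sum(
                _interp(conc_series.get(s.compound_id, ()), day) * s.n_protons
                for s in cat.signals.values()
                if s.aggregate_member_of == cid
            )
        return _interp(conc_series.get(cid, ()), day)

    days = sorted({d for pts in conc_series.values() for d, _ in pts} | set(range(17)))
    targets = [
        s
        for s in cat.signals.values()
        if s.role in ("quantifier", "reference")
    ]
    rendered = [
        s
        for s in cat.signals.values()
        if not cat.compounds[s.compound_id].aggregate
    ]

    candidates: list[tuple[float, str, str]] = []
    for tgt in targets:
        t_cid = cat.compounds[tgt.compound_id]
        own_frac = window_fraction(tgt.center, *tgt.window, fwhm)
        for src in rendered:
            if src.compound_id == tgt.compound_id:
                continue
            if src.aggregate_member_of == tgt.compound_id:
                continue  # intended content of a collective window, not a leak
            leak = window_fraction(src.center, *tgt.window, fwhm)
            if leak <= 0:
                continue
            worst = 0.0
            for day in days:
                if t_cid.id == cat.reference_compound.id:
                    tv = 1000.0  # the reference is 1 mol TG / mol TG throughout
                else:
                    tv = series_at(tgt.compound_id, day)
                if tv < floor:
                    continue
                sv = series_at(src.compound_id, day)
                denom = tv * tgt.n_protons * max(own_frac, 1e-9)
                worst = max(worst, sv * src.n_protons * leak / denom)
            if worst > impact_threshold:
                contained = tgt.window[0] <= src.center <= tgt.window[1]
                candidates.append((contained, worst, src.signal_id, tgt.signal_id))

    # peaks physically inside a foreign window must be corrected (the audit
    # demands it); mere tail leakage is ranked by impact after those
    candidates.sort(key=lambda t: (not t[0], -t[1], t[2], t[3]))

    # greedy, cycle-free at the *compound* level: a correction needs the
    # contributor's compound quantified before the target's window is usable
    comp_adj: dict[str, set[str]] = {cid: set() for cid in cat.compounds}
    for s in cat.signals.values():
        for j in s.corrections:
            comp_adj[cat.signals[j].compound_id].add(s.compound_id)

    def reaches(frm: str, to: str, seen: set[str]) -> bool:
        if frm == to:
            return True
        seen.add(frm)
        return any(reaches(d, to, seen) for d in comp_adj[frm] if d not in seen)

    accepted: list[tuple[str, str]] = []
    have: set[tuple[str, str]] = {
        (j, s.signal_id) for s in cat.signals.values() for j in s.corrections
    }
    for _, _, src_id, tgt_id in candidates:
        if (src_id, tgt_id) in have:
            continue
        c_src = cat.signals[src_id].compound_id
        c_tgt = cat.signals[tgt_id].compound_id
        if c_src != ref_cid:
            # the reference's concentration is known a priori, so it never
            # constrains the quantification order; everything else does
            if reaches(c_tgt, c_src, set()):
                continue  # would make the two compounds mutually dependent
            comp_adj[c_src].add(c_tgt)
        have.add((src_id, tgt_id))
        accepted.append((src_id, tgt_id))
    return sorted(accepted)


def _interp(points: Sequence[tuple[float, float]], day: float) -> float:
    """Piecewise-linear interpolation, zero before the first anchor."""
    pts = sorted(points)
    if not pts or day < pts[0][0]:
        return 0.0
    if day >= pts[-1][0]:
        return pts[-1][1]
    for (d0, c0), (d1, c1) in zip(pts, pts[1:]):
        if d0 <= day <= d1:
            return c0 + (c1 - c0) * (day - d0) / (d1 - d0)
    return 0.0


# ---------------------------------------------------------------------------
# file round-trip (one row per signal, compound fields denormalised)
# ---------------------------------------------------------------------------

_COLUMNS = [
    "signal_id",
    "compound_id",
    "compound_name",
    "category",
    "first_detected_day",
    "aggregate",
    "compound_notes",
    "center_ppm",
    "window_lo",
    "window_hi",
    "n_protons",
    "multiplicity",
    "role",
    "corrections",
    "assumed",
    "aggregate_member_of",
    "notes",
]


def save_catalogue(cat: Catalogue, path: str | Path) -> None:
    """Write a catalogue as a UTF-8 CSV, one row per signal."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        _write_rows(cat, fh)


def _write_rows(cat: Catalogue, fh) -> None:
    w = csv.DictWriter(fh, fieldnames=_COLUMNS)
    w.writeheader()
    # compounds without any catalogued signal (acyl classes quantified only
    # indirectly) are preserved as compound-only rows
    with_sig = {s.compound_id for s in cat.signals.values()}
    for cid in sorted(set(cat.compounds) - with_sig):
        c = cat.compounds[cid]
        w.writerow(
            {
                "signal_id": "",
                "compound_id": c.id,
                "compound_name": c.name,
                "category": c.category,
                "first_detected_day": "" if c.first_detected_day is None else c.first_detected_day,
                "aggregate": int(c.aggregate),
                "compound_notes": c.notes,
            }
        )
    for sid in sorted(cat.signals):
        s = cat.signals[sid]
        c = cat.compounds[s.compound_id]
        w.writerow(
            {
                "signal_id": s.signal_id,
                "compound_id": c.id,
                "compound_name": c.name,
                "category": c.category,
                "first_detected_day": "" if c.first_detected_day is None else c.first_detected_day,
                "aggregate": int(c.aggregate),
                "compound_notes": c.notes,
                "center_ppm": repr(s.center),
                "window_lo": repr(s.window[0]),
                "window_hi": repr(s.window[1]),
                "n_protons": s.n_protons,
                "multiplicity": s.multiplicity,
                "role": s.role,
                "corrections": ";".join(s.corrections),
                "assumed": int(s.assumed),
                "aggregate_member_of": s.aggregate_member_of,
                "notes": s.notes,
            }
        )


def load_catalogue(path: str | Path, field_mhz: float = 400.0) -> Catalogue:
    """Load and validate a catalogue CSV (see :func:`save_catalogue` schema).

    Raises
    ------
    CatalogueError
        on duplicate ids, unresolved references, correction cycles, a missing
        or ambiguous internal-reference signal, or malformed fields.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        return _read_rows(fh, field_mhz)


def _read_rows(fh, field_mhz: float) -> Catalogue:
    rdr = csv.DictReader(fh)
    compounds: dict[str, CompoundClass] = {}
    signals: dict[str, SignalAssignment] = {}
    for row in rdr:
        fdd = row.get("first_detected_day", "")
        comp = CompoundClass(
            id=row["compound_id"],
            name=row["compound_name"],
            category=row["category"],
            first_detected_day=float(fdd) if fdd not in ("", None) else None,
            aggregate=bool(int(row.get("aggregate") or 0)),
            notes=row.get("compound_notes", ""),
        )
        prev = compounds.get(comp.id)
        if prev is not None and prev != comp:
            raise CatalogueError(f"inconsistent compound fields for {comp.id!r}")
        compounds[comp.id] = comp

        sid = row["signal_id"]
        if not sid:
            continue  # compound-only row
        if sid in signals:
            raise CatalogueError(f"duplicate signal_id {sid!r}")
        corrections = tuple(t for t in (row.get("corrections") or "").split(";") if t)
        signals[sid] = SignalAssignment(
            signal_id=sid,
            compound_id=comp.id,
            center=float(row["center_ppm"]),
            window=(float(row["window_lo"]), float(row["window_hi"])),
            n_protons=int(row["n_protons"]),
            multiplicity=row.get("multiplicity", "m"),
            role=row.get("role", "quantifier"),
            corrections=corrections,
            assumed=bool(int(row.get("assumed") or 0)),
            aggregate_member_of=row.get("aggregate_member_of") or "",
            notes=row.get("notes", ""),
        )
    return Catalogue(compounds=compounds, signals=signals, field_mhz=field_mhz).validate()


def default_catalogue() -> Catalogue:
    """The packaged assignment catalogue (corn oil at 400 MHz)."""
    from importlib.resources import files

    text = files("oxynmr.data").joinpath("catalogue.csv").read_text(encoding="utf-8")
    return _read_rows(_io.StringIO(text), 400.0)
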