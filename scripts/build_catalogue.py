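"""Regenerate the packaged catalogue CSV.

Merges the base assignment entries with the tail-leakage correction edges
generated against the packaged trajectory fixture, then writes
``src/oxynmr/data/catalogue.csv``.  Run from the repository root::

    python scripts/build_catalogue.py
"""

from __future__ import annotations

import sys
from dataclasses import replace
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from oxynmr._entries import base_catalogue
from oxynmr.catalogue import Catalogue, save_catalogue, suggest_correction_edges
from oxynmr.synth import packaged_fixture


def built_catalogue() -> Catalogue:
    cat = base_catalogue().validate()
    edges = suggest_correction_edges(cat, packaged_fixture().as_points())
    sigs = dict(cat.signals)
    for src, tgt in edges:
        s = sigs[tgt]
        if src not in s.corrections:
            sigs[tgt] = replace(s, corrections=s.corrections + (src,))
    return Catalogue(compounds=cat.compounds, signals=sigs, field_mhz=cat.field_mhz).validate()


def main() -> None:
    cat = built_catalogue()
    out = Path(__file__).resolve().parents[1] / "src" / "oxynmr" / "data" / "catalogue.csv"
    save_catalogue(cat, out)
    n_edges = sum(len(s.corrections) for s in cat.signals.values())
    print(f"wrote {out} ({len(cat.compounds)} compounds, {len(cat.signals)} signals, "
          f"{n_edges} correction edges)")


if __name__ == "__main__":
    main()
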