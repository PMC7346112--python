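# oxynmr

Quantitative ¹H NMR monitoring of edible-oil oxidation, built for the
model case of a refined corn oil (rich in omega-6 linoleic acyl groups)
held under accelerated-storage conditions (70 °C, aeration) for 16 days.
It is aimed at lipid-oxidation and food-chemistry researchers who want a
reproducible, scriptable version of the qNMR workflow: a machine-readable
signal-assignment catalogue for the oxylipins formed (hydroperoxy-,
hydroxy-, keto-, epoxy-dienes and -monoenes, aldehydes, formates,
poly-ethers, sterol oxides), window integration with overlap corrections,
internal-reference quantification, and stage-wise kinetics.

## The core calculation

Because all protons relax fully between scans, every signal's area is
proportional to concentration × proton count with a single proportionality
constant. Using the triglyceride glyceryl *sn*-1/*sn*-3 protons (4 per TG,
negligible hydrolysis) as internal reference, the concentration of a
functional group X is

```
[X] = (A_X / n) / (A_TG / 4) × 1000      [mmol / mol TG]
```

where `A_X` is the integrated area of X's selected signal and `n` the number
of protons generating it. Overlapping windows are handled by *area
bookkeeping*: co-resonant contributors are quantified first from clean
windows, their predicted in-window Lorentzian mass (via `A_TG/4`) is
subtracted, and each area is divided by the analytic in-window fraction of
its own lineshape so heterogeneous window widths do not bias the ratio.
Kinetics are per-stage ordinary-least-squares slopes over the breakpoints
day 0 / 8 / 11 / 14 / 16, plus appearance / maximum / disappearance events
against a detection limit (default 0.5 mmol/mol TG).

A synthetic-spectrum generator stands in for the instrument: it renders any
concentration state into a 400 MHz spectrum in which every catalogued signal
is a Lorentzian with exactly the proportional area the formula assumes, and a
packaged trajectory fixture encodes the 16-day oxidation course anchored at
reported concentrations. That makes every stage of the pipeline testable
end-to-end with no data download.

## Worked example

```python
from oxynmr import (default_catalogue, packaged_fixture, make_timecourse,
                    render_spectrum, quantify_spectrum, LineshapeParams)

cat = default_catalogue()
tc = make_timecourse(packaged_fixture(), range(17))
sp = render_spectrum(tc.row(13), cat, LineshapeParams(), meta={"day": 13})
res = quantify_spectrum(sp, cat)
print(res.concentrations["mHPO_cEE_dE"], res.concentrations["mHPO_cZE_dE"])
```

prints `140.76 48.47` — the day-13 maxima of the (E,E)- and
(Z,E)-hydroperoxy-conjugated-diene channels (ground truth 140.9 and 48.5
mmol/mol TG), recovered through the full render → integrate → normalise →
correct chain. The narrative scripts in `examples/` show the same machinery
per capability (single-spectrum quantification, stage kinetics, overlap
subtraction); e.g. `python examples/02_timecourse_kinetics.py` prints the
four linoleic stage rates (−7.6, −28.9, −256.7, −126.4 mmol/mol TG per day)
and the 69% / 31% split of linoleic loss into hydroperoxides vs other
products over days 8–11.

## Command line

```
oxynmr simulate --config cfg.yaml      # spectra (JCAMP-DX) + truth table
oxynmr quantify --config cfg.yaml out/*.jdx
oxynmr kinetics out/concentrations.csv --plot
```

All randomness is seeded from the config; identical seeds give byte-identical
spectra files.

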