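# vulvanet

A multi-valued logical model coupling **cell-cycle control** and **vulval
precursor cell (VPC) fate determination** in *Caenorhabditis elegans*, with
the full battery of analyses performed on it: exhaustive attractor and basin
enumeration, cell-cycle phase and fate classification, differentiation and
trans-differentiation simulations, single-mutant and interaction-removal
screens, signed feedback-circuit enumeration, and a continuous sigmoidal
(SQUAD-style) validation of the cell-cycle oscillator.

## The model

Fourteen molecular species form one synchronous, deterministic, multi-valued
network. Two are held inputs describing a VPC's microenvironment — the
inductive EGF-like signal **LIN-3** (levels 0–3) and the Notch-ligand lateral
signal **LS** (0/1). **MPK-1** (Ras/MAPK effector) and the Hox factor
**LIN-39** take levels 0–2; the Notch receptor (**LIN-12m**) and its nuclear
fragment (**LIN-12i**), the CDK inhibitor **CKI-1**, the E2F factor
**EFL-1**, the Rb orthologue **LIN-35**, the ubiquitin ligases **SCF** and
**APC**, and the three CDK/cyclin complexes **CDK-4/CYD-1**, **CDK-2/CYE-1**
(S marker) and **CDK-1/CYB-3** (M marker) are Boolean. A state is
`x = (x₁, …, x₁₄)`; all nodes update together,

```
xᵢ(t+1) = fᵢ(x(t)),    i = 1 … 14,
```

over the 4·3·3·2¹¹ = 73,728 reachable configurations. Fates are read off
attractors: LIN-39 at level 2 marks the primary fate, LIN-12i activity the
secondary, LIN-39 held at its basal level 1 without LIN-12i the tertiary,
and LIN-39 silenced throughout marks fusion with the hypodermis. The
continuous companion model relaxes the eight cell-cycle rules to

```
dXᵢ/dt = A_h(ωᵢ(X)) − γ·Xᵢ,    A_h a normalized sigmoid (h = 10, γ = 0.95),
```

with ωᵢ the min/max (fuzzy AND/OR) reading of the discrete logic.

## Worked example

```python
from vulvanet import build_wildtype_model, find_attractors, basin_summary

model = build_wildtype_model()
attractors = find_attractors(model)          # exhaustive, all 73,728 states
basins = basin_summary(model, attractors)
for a, size in zip(attractors, basins.sizes):
    print(a.inputs, a.period, a.fate, a.g1_length, size)
```

prints

```
(0, 0) 11 tertiary 6 9216
(0, 1) 11 secondary 6 9216
(1, 0) 10 secondary 5 9216
(1, 1) 11 secondary 6 9216
(2, 1) 9 secondary 4 9216
(2, 0) 9 primary 4 9216
(3, 0) 9 primary 4 9216
(3, 1) 9 primary 4 9216
```

Eight cyclic attractors, exactly one per (LIN-3, LS) microenvironment, each
draining an equal basin of 9,216 states: every microenvironment commits the
cell to a single fate, and Ras signalling shortens the cell cycle (9 steps
with 4 G1 states under strong LIN-3, 11 steps with 6 G1 states in the
tertiary/VPC context) by repressing the CDK inhibitor CKI-1.

The same analyses are available from the command line
(`vulvanet attractors|basins|fate-transitions|mutants|removals|circuits|squad|validate`)
and as narrative drivers under `analysis/`:

```sh
python analysis/01_attractors_and_basins.py
python analysis/04_removal_screen.py   # 12 of 38 removals leave the dynamics unchanged
python analysis/05_feedback_circuits.py
python analysis/06_continuous_cell_cycle.py
```

The circuit census deserves one caveat: the curated 38-edge interaction
graph contains 111 simple feedback circuits, 59 positive and 52 negative by
the rule-derived edge signs. The originally published census splits the same
111 loops 60/51 because of two internal defects of its tables (an edge
glyph contradicting the update rule in four rows, and one row filed against
its own glyphs); `analysis/05_feedback_circuits.py` lists the affected rows.

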