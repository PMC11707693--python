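# exphar

Exponential Hirshfeld partitioning of molecular electron density, aspherical
atomic form factors, a minimal Hirshfeld-atom-style refinement engine, and
ADP similarity statistics — a desk-scale laboratory for studying how the
choice of stockholder partition propagates into refined hydrogen-atom
parameters in small-molecule crystallography.

## The problem

Hirshfeld atom refinement (HAR) refines crystal structures against X-ray
data using form factors of stockholder-partitioned atomic electron
densities. Hydrogen parameters from HAR are sensitive to errors in the
parameters of the bonded neighbour: the more the atomic densities overlap,
the more a wrong neighbour ADP (anisotropic displacement parameter) is
compensated by distorting the hydrogen ADP, typically inflating it along
the X—H bond. The *exponential Hirshfeld* partition

```
w_A(r) = rho°_A(r)^n / sum_B rho°_B(r)^n ,      rho_A(r) = w_A(r) rho(r)
```

raises the isolated-atom (promolecule) densities `rho°` to a power `n >= 1`.
`n = 1` is the classic Hirshfeld partition; larger `n` shrinks the
interatomic density overlap and thereby the hydrogen atom's exposure to its
neighbour's errors. This package implements the partition, the numerical
form factors of the partitioned densities (`.tsc` tables), an F²
least-squares refiner with SHELX-type weights that consumes them, the ADP
comparison statistics

* `MSD_corr` — Pearson-style correlation of the directional mean-square
  displacements `MSD_n(U) = nᵀUn` of two ADPs over all directions
  (scale- and shift-invariant; undefined for isotropic U),
* the overlapping coefficient `OVL = 1 − η`, `η = ½∫|p₁ − p₂| d³u` of the
  two displacement PDFs, and its percent form `η_r`,
* the Gaussian correlation coefficient `CC = √8 (det U₁ det U₂)^¼ /
  det(U₁+U₂)^½` with `S₁₂ = 100(1 − CC)`,
* the isotropic ADP scale `q = argmin Σ‖U_ref − q U_tgt‖²_F`,

and a seeded synthetic-crystal generator used to reproduce the
neighbour-ADP-bias mechanism end to end.

## Worked example

```python
import numpy as np, exphar as xp

# the directional-MSD correlation of two diagonal ADPs
xp.msd_corr(np.diag([2, 1, 1]), np.diag([1, 2, 1]))     # -> -0.5

# a one-electron two-centre "H2+" toy: charges are +0.5 by symmetry for
# every exponent, while the interatomic overlap falls with n
toy = xp.TwoCenterDensity(2.0)                           # 2 bohr separation
for n in (1, 2, 4):
    spec = xp.PartitionSpec(n, toy.sites)
    q = xp.atomic_charge(0, spec, toy)
    o = xp.overlap_coefficient(0, 1, spec, toy)
    print(f"n={n}: q_A={q:.4f}  o_AB={o:.4f}")
# n=1: q_A=0.5000  o_AB=0.3124
# n=2: q_A=0.5000  o_AB=0.1561
# n=4: q_A=0.5000  o_AB=0.0793

# the neighbour-bias experiment: heavy-atom U fixed to 0.9x truth,
# hydrogen refined with the exponent-n partition (noise-free data)
rep = xp.neighbor_bias_experiment("diatomic_XH", q_fix_list=(0.9,),
                                  n_list=(1.0, 2.0, 4.0),
                                  d_min_list=(0.8,), seed=1)
print(rep.records[["exponent", "bond_msd_excess",
                   "ueq_ratio_vs_truth", "msd_corr_vs_truth"]])
#    exponent  bond_msd_excess  ueq_ratio_vs_truth  msd_corr_vs_truth
# 0       1.0         0.019536            1.040027          -0.622510
# 1       2.0         0.009454            0.964735          -0.080898
# 2       4.0         0.006773            0.952927           0.380680
```

Reading the output: with the neighbour's ADP deliberately 10 % too small,
the refined hydrogen ADP at `n = 1` is inflated along the bond
(`bond_msd_excess = +0.0195 Å²`, `U_eq` 4 % too large) and points the wrong
way (`MSD_corr = −0.62` against truth). Raising the exponent to 2 and 4
halves the bond-direction excess and restores the ellipsoid orientation —
the mechanism, and its mitigation, that motivates the exponential
partition. With `q_fix = 1` (an unbiased control) every exponent recovers
the truth exactly.

A `exphar` console script exposes the same operations
(`exphar simulate | charges | overlap | tsc | refine | compare-adps |
experiment neighbor-bias`); run `exphar --help`.

## Scope

Quantum-chemical densities (DFT/HF/MP2 wavefunctions), multipole
crystal-field embedding, space groups beyond P1 and re-refinement of
published experimental datasets are out of scope; the shipped isolated-atom
densities are single-zeta Slater 1s models behind a pluggable interface,
and all claims tested here are the partition-algebra, statistics and
mechanism properties that do not depend on the density source. See
`docs/methods.md` for the model details and numerical choices.
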