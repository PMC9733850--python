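# lamellaflex

Analysis of supported lipid multilayers (SLMs) under lateral compression.

When a stack of lipid bilayers sits on a compliant elastomer (e.g. PDMS)
and the substrate is compressed, the film reorganizes at several length
scales at once: it wrinkles and detaches in delamination buckles at the
micron scale, its diffraction peaks shift and broaden at the molecular
scale, and in coarse-grained simulations its lipids tilt collectively on
nanoscale undulations. `lamellaflex` provides the quantitative analyses
for all three observations, plus seeded synthetic-data generators for
every input, so each analysis can be validated end-to-end against known
ground truth.

The package is intended for soft-matter and membrane-biophysics groups
analysing AFM topographies, 1D grazing-incidence scattering profiles
(GISAXS/GIWAXS) and coarse-grained multilayer configurations.

## The models

**Buckle delamination (`ruga`).** For a delaminated buckle of width λ in
a film of thickness *t* under substrate strain ε, energy balance between
bending, compression and adhesion gives

    λ / t^(3/2) = π √(2 E̅_f ε / Γ)

with in-plane film modulus E̅_f and film–substrate adhesion energy Γ.
The relation is linear in √ε after normalizing widths by t^(3/2), so a
through-origin regression of λ/t^(3/2) on √ε yields a slope *m* and
Γ̂ = 2π² E̅_f / m², with a delta-method standard error from the slope SE.

**Scattering (`scattering`).** Diffraction peaks in azimuthally
integrated profiles are fit as Lorentzians on a linear background; the
fitted position converts to a real-space spacing d = 2π/q₀ and the FWHM
to an apparent correlation length ξ = 2π/FWHM. Lamellar series
q_n = 2πn/d are indexed and reduced to one repeat distance.

**Orientational order (`order`).** Each lipid's director runs from its
head bead to the mean of its terminal bead(s); tilt is the director's
angle to the membrane normal, folded to [0°, 90°]. Chain order is the
second-rank order parameter P₂ = ⟨(3cos²θ − 1)/2⟩ over bond vectors,
measured against the normal (tilt + conformational disorder) or against
each lipid's own director (conformational disorder only). Inter-layer
cooperativity is the segment-wise tilt correlation
⟨θ(l₁)θ(l₂)⟩/⟨θ(l₁)θ(l₁)⟩ over lipid pairs sharing a lateral bin.

## Worked example

```sh
python examples/adhesion_energy.py
```

```
adhesion energy Gamma = 0.212 +/- 0.008 J/m^2 (slope 62549 m^-1/2, n=12)
```

Twelve synthetic buckles were generated from the width law at
Γ = 0.22 J/m², E̅_f = 42 MPa, strains {5, 10, 14}% with 10% measurement
noise on λ; the inversion recovers the generating adhesion energy to
within a few percent. The other examples run the same way:

* `examples/scattering_peaks.py` — fits a chain-packing peak at
  q ≈ 1.51 Å⁻¹ (spacing 4.15 Å, ξ ≈ 103 Å) and a lamellar pair giving a
  5.6 nm repeat;
* `examples/tilt_and_order.py` — an undulated 4-layer stack with maximum
  slope tan 22.5° puts the tilt-histogram mode at 22.5°, P₂ vs the
  normal at 0.886 and director-renormalized P₂ at exactly 1;
* `examples/topography_roughness.py` — a 6.2225 nm sinusoidal wrinkle
  field has RMS roughness 4.40 nm, and a constructed 600 nm buckle is
  recovered at 610 nm width;
* `examples/full_pipeline.py` — the whole simulate → analyze → fit
  pipeline from `examples/demo_config.json`.

A thin CLI mirrors the library:

```sh
lamellaflex simulate buckles --n 12 --rel-noise 0.1 --seed 1 --out buckles.tsv
lamellaflex fit-adhesion buckles.tsv --e-mpa 42
```

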