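# Methods

## Physical model

The chamber is one well of a 12-well plate with two parallel graphite
plate electrodes reaching to the bottom, driven with symmetric biphasic
rectangular voltage pulses. The medium is treated as a homogeneous,
purely conductive ohmic liquid: at the stimulation frequencies used
(≈8–20 Hz) displacement currents and any frequency dependence of the
medium's dielectric response are negligible, so at every instant the
potential solves the electrostatic Laplace equation

    ∇·(∇φ) = 0   in the liquid cross-section,

with Dirichlet values ±V/2 on the two electrode boundaries and zero
normal current on the insulating well wall. The model is two-dimensional:
a horizontal slice through the liquid, valid where the field is
depth-independent (plates are vertical and reach the bottom; the free
surface and dish bottom are insulating). Consequences of the 2D
idealization: the computed electrode current is a per-depth quantity
(A/m) and is converted to amperes by multiplying with the liquid fill
level h; meniscus/capillary effects and the vertical field disturbance
near the liquid surface are outside the model.

The problem is linear in the applied voltage, so all solves are done at
1 V and rescaled. It is likewise linear in the conductivity σ, which
enters only as a multiplier on currents.

Not modeled, deliberately: the capacitive electrode–electrolyte double
layer and faradaic reactions at the graphite surface. These change the
pulse shape and increase the measured peak current relative to the
purely conductive prediction; the validation module quantifies (but does
not explain) that gap.

## Geometry calibration

Two chamber dimensions are fixed by the published characterization of
this stimulation system: the electrode gap d = 11 mm and a wetted
electrode area of 0.42 cm² at 1 mL fill, together with the 3.4 mm fill
level at 1 mL. The remaining dimensions are reconstructed:

| parameter | default | origin |
|---|---|---|
| electrode gap d | 11 mm | stated |
| fill level h at 1 mL | 3.4 mm | stated |
| electrode width w | 12.35 mm | 0.42 cm² / 3.4 mm |
| effective liquid area | 2.94 cm² | 1 mL / 3.4 mm |
| well diameter | 22.1 mm | nominal 12-well plate |
| electrode thickness | 1 mm | assumed |
| conductivity σ | 1.3 S/m | measured medium value (DMEM + 10% FCS) |

Choices made where the record is ambiguous:

- The 0.42 cm² wetted area is interpreted as the wetted face of **one**
  electrode; this yields a plausible 12.35 mm plate inside a 22.1 mm
  well (the both-electrodes reading would give a 6.2 mm plate, much
  narrower than the chamber photographs suggest).
- A 1 mL fill in a plain 22.1 mm cylinder would stand only 2.6 mm high,
  not 3.4 mm; the electrode assembly evidently displaces volume. The
  fill level is therefore a direct input (default 3.4 mm) and the
  *effective* liquid area 2.94 cm² = 1 mL / 3.4 mm is the calibration
  constant used for volume→level conversion, rather than πr².
- Electrode thickness only shapes the low-field shadow behind the
  plates; 1 mm is assumed and configurable.

Reconstruction uncertainty matters most for the electrode current: the
flux integral picks up fringing contributions from the plate edges and
the return path around the plate backs, so it is sensitive to the plate
width and well diameter at the ~5% level per millimeter-scale change
(e.g. widening the well to 24 mm or the plate to 14 mm raises I₂D from
1.69 to 1.77 A/m at 1 V, σ = 1 S/m). The centerline field values are far
less sensitive (<1%). Reported currents should therefore be read with a
few-percent geometry uncertainty attached.

## Discretization and numerics

- **Meshing.** The liquid cross-section (disc minus two rectangles) is
  triangulated from a deterministic point set: boundary walks along the
  circle and rectangle edges plus multi-level hexagonal interior
  lattices, Delaunay-triangulated (scipy) and filtered by a centroid
  test. The local edge length shrinks 4× toward the four electrode
  corners, where the reentrant-corner field singularity lives; the
  grading slope is 0.5 (edge length recovers the target within ~1.5 mm
  of a corner). No randomness is involved, so meshes are reproducible
  without a seed. Default target edge length: 0.5 mm (about 3 400
  triangles); the characterization script uses 0.25 mm.
- **Elements and solver.** P1 (piecewise-linear) triangles, assembled
  into the standard stiffness matrix; Dirichlet elimination; direct
  sparse factorization (`scipy.sparse.linalg.spsolve`). The quantities
  of interest are low-order functionals, and on a rectangle with
  full-width electrodes the exact linear-ramp solution lies in the P1
  space — that closed form is the solver's machine-precision oracle in
  the tests. Every solve checks the discrete maximum principle
  (extrema of φ on the Dirichlet nodes).
- **Field evaluation.** The per-element constant field is averaged to
  nodes with area weights and interpolated linearly for point queries
  (centerline profile, symmetry checks); point queries landing on a node
  thus return the area-weighted average of the adjacent elements.
  Area-fraction statistics (homogeneity bands) use the raw per-element
  field.
- **Electrode current.** The consistent boundary-flux formulation:
  summing the stiffness residual Kφ over one electrode's Dirichlet
  nodes equals ∮ ∇φ·n weighted by the hat functions, which converges
  faster than integrating sampled gradients along the boundary. The two
  electrode integrals are checked to cancel to <1% (they cancel to
  machine precision here, since the discrete system enforces flux
  balance exactly on the free nodes).
- **Convergence.** Between 0.5 mm and 0.25 mm meshes the midpoint field
  moves by 0.02% and the per-depth current by 0.14%; the corner
  singularity makes the current the slowest-converging output.

At 1 V on the default geometry the model gives a centerline field
falling from ≈92.2 V/m at the electrode faces to ≈89.6 V/m at the
midpoint (infinite-plate limit: 90.91 V/m) and I₂D ≈ 1.69 A/m at
σ = 1 S/m, i.e. 5.7 mA per well at 1 S/m and 7.5 mA at 1.3 S/m. Note the
whole-section homogeneity fraction is modest (≈38% of the liquid area
lies within 80–100 V/m at 1 V) because the regions behind the plates and
beyond the plate edges see a weak field; between the plates, where the
cells under study sit, the field is uniform to within a few percent
except at the corners.

## Pulse dosimetry

τ is the **total** biphasic duration: each polarity lasts τ/2, so the
stimulator settings (20 Hz, 3.6 ms) and (7.9 Hz, 10 ms) have duty cycles
f·τ = 0.072 and 0.079. For rectangular pulses the instantaneous power
during a pulse is V·I_peak regardless of polarity, giving the closed
forms

    P_avg = V · I_peak · f·τ,      E = P_avg · t_session,
    ΔT_max = E / (ρ c_p V_liquid),

with water thermal properties (ρ = 1000 kg/m³, c_p = 4184 J kg⁻¹ K⁻¹)
as medium defaults and a 600 s session as the protocol default. ΔT_max
is an adiabatic upper bound; real wells lose heat to the plate and
incubator air. The dose table's power/energy column uses the
model-predicted (theoretical) current; with the measured peak currents
the same formulas give ~1.6–1.8× larger values, and the prediction
ratios in the validation report make that translation explicit.

## Validation diagnostics

Measured currents are shunt-resistor peak values (R = 1 Ω), taken as
pulse-top amplitudes with no transient correction. Two diagnostics:

- voltage-scaling factor I(5 V)/I(1 V) per frequency, compared with the
  ideal ratio 5; a relative deviation >5% raises an informational
  linearity flag (the packaged measurements give 5.6 at 20 Hz and 5.75
  at 7.9 Hz — close to, but not perfectly, linear);
- prediction ratio measured/predicted per setting (≈1.6 at 1 V with the
  packaged measurements), the unexplained gap attributed to the
  unmodeled electrode interface, conductivity measurement error, or the
  capillary rise not captured in 2D.

## Synthetic data

`synth_current_trace` emulates the shunt observable: the ideal biphasic
rectangular train at the stimulator timing scaled to a target pulse-top
peak, plus i.i.d. zero-mean Gaussian noise (instrumentation-amplifier
model; an optional mains-frequency sinusoid can be added). It does
**not** emulate finite amplifier bandwidth, pulse rise times, capacitive
overshoot or drift — so peak-detector round-trip tests demonstrate
noise robustness, not immunity to shape distortion. The matching
detector averages |I| over samples above 80% of the 99.9th percentile,
a pulse-top mean that is unbiased to ~1% at 5% relative noise and never
keys on a single maximum sample. `perturbed_geometries` jitters gap,
width and fill level multiplicatively (Gaussian, relative SD < 0.2,
invalid draws resampled) for sensitivity studies like the one quoted
above.

## Degenerate inputs and tie-breaks

Zero applied voltage returns the identically-zero field (and cannot be
rescaled); zero liquid volume maps to zero fill level, which the chamber
type rejects as unphysical; an all-zero trace yields a zero peak
estimate; a measurement table lacking a voltage level makes the scaling
factor unavailable (error) rather than silently degrading. Boundary
edges are tagged by midpoint location, so an edge joining an electrode
corner to the wall belongs to the wall (Neumann), keeping the Dirichlet
set exactly on the plates.

## Known limitations

- 2D quasi-static conduction only: no double-layer charging, no
  faradaic chemistry, no 3D end effects, no meniscus.
- The unpublished plate width/well diameter bound the current
  prediction's accuracy to a few percent (see above); the field values
  are robust.
- The adiabatic ΔT bound is intentionally loose (no heat-loss model).
- The synthetic trace generator's noise model is nominal; real
  instrument noise levels and rise times were not characterized.
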