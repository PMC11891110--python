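# Methods note

This note documents the models, conventions and design choices behind
`axskel`, in the order the pipeline runs them.

## Working grid and coordinate conventions

All segmentation and PET logic runs on a fixed 4 × 4 × 4 mm grid, the
resolution PET is reconstructed at in the intended application; CT inputs
and label masks are resampled on load (linear interpolation for
intensities, nearest neighbour for labels — the resampling interpolator is
not dictated by the protocol, so the common default was chosen and is
stated here). Arrays use a canonical "LAS" index order — axis 0 toward
patient-left, axis 1 anterior, axis 2 superior — so "anterior of" and
"left of" are plain index comparisons. The mm coordinate of voxel
`(i,j,k)` is `origin + index * spacing` (voxel-center convention). On
disk, volumes are RAS+ NIfTI; axis 0 is flipped on the way in and out.

Structuring elements: sphere offsets are exactly the lattice points whose
center-to-center distance is ≤ the radius (81 voxels for 10 mm at 4 mm
spacing, 7 for 4 mm). The vertical line element spans ±round(L/spacing)
voxels craniocaudally, i.e. ±3/±2/±1 for the 12/8/4 mm regional lengths;
the one-sided reading keeps the cervical element non-degenerate. Rounding
of continuous voxel coordinates is half-away-from-zero.

## Morphological method

Per axial slice the spinal cord provides a reference point: the most
anterior cord voxel for C1–T3 (these vertebrae carry relatively anterior
transverse processes), the cord-slice center for T4–L5. Vertebra voxels
strictly anterior of the reference are VB; the reference column itself
counts as posterior (the tie-break is documented rather than principled —
either choice moves single columns only). Slices with vertebra but no
cord voxels borrow the nearest cord slice's reference and raise a QC
flag. The posterior remainder splits left/right at the sagittal plane
through the whole-cord center of mass; the whole-volume COM (rather than
per-slice) is robust to cord wiggle.

Disks: overlap of the two vertically dilated adjacent VBs minus the
original bone segmentation. Joints: both partner bones are iteratively
dilated with the 4 mm sphere (capped at 5 rounds to bound runtime) until
they meet; the joint center is the COM of the overlap rounded to a voxel,
and the SIJ keeps the overlap-minus-bone volume instead. Partner
assignment: FJs pair the posterior parts of *adjacent* levels (facet
joints lie between vertebrae); the L5–S1 facet pairs L5's posterior part
with the whole sacrum, which has no VB/posterior split. CVJs pair a rib
with its same-level VB (rib head), CTJs with the same-level ipsilateral
posterior part (rib tubercle on the transverse process); CTJs exist for
T1–T10 only — the T11/T12 ribs lack costotransverse articulations — fixing
the 20-joint inventory.

## Multi-atlas method

Spinal length is the mm distance between the C1 and sacrum COMs. Atlas
ranks use the nearest-rank (ceiling) percentile convention on the
ascending sort, stepping duplicates to the next unused rank; for n = 45
this yields 1-based ranks 5, 14, 23, 32, 41. (No single standard
convention reproduces a 90th-percentile rank of 39 for n = 45; the
convention here is fixed and stated rather than reverse-engineered.)

Each atlas scan is cut into 26 partial atlases: the tight joint bounding
box of the two member structures plus a 2-voxel margin, cropped from the
intensity image and from the reference label map (codes: upper structure
/ disk-or-SIJ / lower structure), with the unit's joint-center points
stored in mm. At desk scale, the morphological output of the atlas scan
stands in for the manually drawn reference labels.

Registration is similarity (rigid + isotropic scale): mean-squares
metric, regular-step gradient descent, 100 iterations, two-level
multi-resolution, geometric-center initialisation, and full (not
sampled) metric evaluation so runs are deterministic. The fixed crop is
zero-padded by 10 voxels beforehand, which stops the moving image from
scaling uncontrolledly outside the fixed box. The backend is pluggable
behind the `register_similarity` contract; SimpleITK provides the
reference implementation. Recovered transforms map fixed-frame physical
points to moving-frame points; label maps are propagated by
nearest-neighbour resampling and points by the inverse map.

Fusion: per voxel and label, foreground iff ≥ 3 of 5 atlases agree (a
strict majority is unique); joint centers are the component-wise mean of
the five propagated points, rounded to a voxel. Fused unit boxes are
re-integrated craniocaudally, SIJ units last; later units never overwrite
earlier non-background voxels.

## VOI composition

Each VB splits into 8 quadrants: the VB bounding box within the COM
mid-sagittal slice provides four corner landmarks (the protocol's corner
definition is ambiguous; the bounding-box corners are the only
parameter-free reading), every VB voxel goes to the nearest corner by its
(anteroposterior, craniocaudal) mm coordinates — distance ties go to the
earlier corner in the order AS, AI, PS, PI — and left/right splits at the
COM sagittal plane. A DVU is inferior quadrants (upper VB) + disk +
superior quadrants (lower VB); the 24-unit inventory runs C1–C2 through
L5–S1, the sacral contribution using the same quadrant rule on the sacrum
mask. The C1–C2 unit may legitimately have an empty disk. Point joints
become closed-ball spheres of radius 10 mm clipped at the grid boundary;
radii below the spacing leave the single center voxel.

## Validation metrics

DSC = 2|A∩B|/(|A|+|B|), defined as 1 for two empty masks. The average
Hausdorff distance is the symmetric variant — mean over A of the nearest
distance to B, averaged with the reverse direction — in mm between voxel
centers; the symmetric mean-of-directed-means is the common default where
the direction is unspecified. Error distances are Euclidean between
joint-center voxel centers, reported to 2 decimals; one-voxel axial and
in-plane diagonal offsets give the characteristic 4.00 and 5.66 mm.
Test–retest: the scan-2 spine bone mask is rigidly registered onto scan 1
(same backend, scale locked to 1), the transform realigns scan 2's output
masks (nearest neighbour) and centers (inverse map), and the three
metrics are computed over the VOI inventory. Method comparison reports
per-structure paired differences (second minus first) as median and IQR
with a rank-sum p-value delegated to scipy.

## Detection

SUVpeak uses a 6 mm-radius spherical neighbourhood, ≈ 1.2 mL / 19 voxels
at 4 mm — an EANM-style 1 mL convention adopted because the protocol does
not define SUVpeak; the neighbourhood mean is computed over the in-grid
part at boundaries. Background SUVmedians come from the input skeletal
labels: cervical = C1–C7, thoracic = T1–T12, lumbar = L1–L5, plus whole
spine, femur, liver and aorta; femur and aorta are eroded one voxel
(6-face-neighbour rule) to shed cortical bone and vascular lumen — this
erosion is also the only misalignment compensation applied. Every VOI's
TBR uses the spine segment of its own level; SIJs use the lumbar
background as the anatomically adjacent segment. Threshold comparisons
are closed (≥). AUC uses the rank/Mann–Whitney formulation (ties count
1/2); the K-S operating threshold maximises TPR − FPR over observed
scores with integer-arithmetic comparison so mathematically tied
thresholds break toward the lower value; cut-offs are selected per VOI
family (DVUs vs joints/SIJs). The DeLong test uses the midrank
("fast") formulation with a two-sided normal p-value.

## Synthetic phantom

The phantom emulates the pipeline's input interface, not anatomy:
vertebrae are cuboid bodies with a posterior arch (pedicles, lateral
masses, lamina/spinous block) so the VB split and FJ geometry are
exercised; thoracic levels carry ribs with head and tubercle blocks
facing the VB and transverse process across one-voxel gaps; sacrum and
ilia meet across an oblique 1–2 voxel gap; femurs, liver and aorta
complete the background-region inventory. Adjacent bones are separated by
at least one soft-tissue voxel — which is exactly where the disks and
joints live. Bone is brighter than soft tissue in HU (LDCT noise sd 20 HU
by default), and an anatomical scale factor (0.8–1.2) plus pose jitter
provide inter-subject variation for atlas work. Default grid ≈ 40 × 42 ×
158 voxels; all randomness flows through the spec seed.

PET backgrounds default to SUVmedian 5/6/7 for cervical/thoracic/lumbar
spine (sacrum and ilia take the lumbar level, ribs the thoracic), femur
2, liver 1, aorta 1.5, soft tissue 0.5 — plausible Na[¹⁸F]F levels with
the cranio-caudal spine gradient. Lesions are additive Gaussian blobs;
ground truth is geometric (a VOI is positive iff a lesion center lies
inside its mask), independent of any uptake threshold, so operating
points can be swept against a fixed truth. The default test lesions are
compact (σ = 2 mm, amplitude ≈ 4 × background) so that at zero noise a
lesion pushes only the VOIs containing its center voxel over the default
cut-offs: one voxel away the added signal is already down to
exp(−8) ≈ 0.14 of the peak, keeping neighbouring VOIs below TBR 1.8.

What the phantom does *not* emulate: realistic bone shape and texture,
scanner point-spread and reconstruction effects, PET–CT misalignment,
degenerative or ankylosed anatomy, and segmentation errors in the input
label mask. Passing tests therefore demonstrate the correctness of the
pipeline's logic and bookkeeping under its stated conventions, not
clinical segmentation accuracy on patient LDCT.

## Problem sizes

Tests and the acceptance script run one phantom scan per configuration, a
five-scan atlas library spanning scales 0.92–1.08, registration-recovery
sweeps of 10–20 seeded transforms on a two-vertebra-scale crop, and
ROC/threshold oracle suites of 100–200 random score sets; the DeLong
variance check uses a 2000-replicate paired bootstrap at n = 300. These
sizes keep the full suite under a couple of minutes on one CPU while
leaving every contract exercised end to end.

## Known limitations

* The atlas method's reference labels at desk scale come from the
  morphological method, so cross-method comparisons on the phantom are
  consistency checks, not independent accuracy estimates.
* Non-rigid registration is out of scope; the similarity model cannot
  absorb shape differences beyond global pose and size.
* The morphological split assumes the cord mask spans the vertebral
  column; heavily cropped scans fall back to nearest-slice references.
* Sphere VOIs at grid borders are clipped, slightly shrinking edge
  joints' VOIs.
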