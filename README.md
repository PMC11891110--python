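# axskel

Automated segmentation of the axial skeleton on low-dose CT (LDCT) for
quantitative Na[¹⁸F]F PET analysis in spondyloarthritis (SpA).

SpA activity concentrates in a specific set of skeletal sites: the
discovertebral units (DVUs — intervertebral disk plus the adjacent
vertebral-body halves), the sacro-iliac joints (SIJs) and the posterior
spinal joints (facet, FJ; costovertebral, CVJ; costotransverse, CTJ).
Reading whole-spine Na[¹⁸F]F PET scans for these sites by eye is slow and
observer-dependent. `axskel` turns a TotalSegmentator-style multi-label
skeletal mask plus the co-registered PET volume into a complete per-site
VOI inventory — **24 DVUs, 48 FJs, 24 CVJs, 20 CTJs and 2 SIJs = 118 VOIs
per scan** — and flags each VOI as positive or negative for pathological
tracer uptake by a threshold rule.

## Methods at a glance

Everything runs on a 4 × 4 × 4 mm working grid matched to the PET
resolution. Two independent segmentation methods are implemented:

**Morphological method.** Each vertebra is split per axial slice at a
spinal-cord landmark (most anterior cord voxel for C1–T3, cord-slice
center for T4–L5): voxels strictly anterior become the vertebral body
(VB), the rest split left/right at the sagittal plane through the cord
center of mass. Disks are the overlap of vertically dilated adjacent VBs
minus bone (element length 12/8/4 mm for lumbar/thoracic/cervical);
SIJs come from iterative 4 mm-sphere dilation of sacrum and ilium. The
posterior joints are segmented as single points — the center of mass of
the dilation overlap of their two partner bones.

**Multi-atlas method.** Atlas scans are picked at the 10th/30th/50th/
70th/90th percentiles of the spinal length (C1-to-sacrum COM distance)
and cut into 26 partial atlases each (24 adjacent-vertebra pairs plus two
sacrum+ilium boxes). Per target unit: crop, zero-pad 10 voxels, register
all five partial atlases with a similarity transform (mean-squares
metric, gradient descent, 100 iterations), propagate the label maps, fuse
by majority voting (≥ 3 of 5), and average the five joint-center
estimates.

DVUs are composed by splitting each VB into 8 quadrants (nearest
bounding-box corner in the mid-sagittal plane, left/right at the COM) and
joining the four inferior quadrants, the disk, and the four superior
quadrants of the vertebra below. Point joints become 10 mm-radius
spherical VOIs.

**Detection.** Per VOI the SUVmax, SUVpeak (6 mm-radius ≈ 1 mL
neighbourhood) and SUVmean are extracted; backgrounds are the SUVmedian
of the cervical/thoracic/lumbar spine (plus whole spine, femur, liver and
one-voxel-eroded aorta/femur). The default rule classifies a VOI positive
when TBR = SUVmax / SUVmedian(matched spine segment) ≥ 1.8 for joints and
SIJs or ≥ 2.25 for DVUs; a raw-SUVmax rule (cut-offs 10.4 / 13.0) is also
provided. ROC/AUC analysis, Kolmogorov–Smirnov threshold selection and
the DeLong test for correlated AUCs support operating-point studies.

Validation metrics: Dice similarity coefficient (DSC), symmetric average
Hausdorff distance, joint-center error distance (on the 4 mm grid a
one-voxel offset is 4.00 mm, an in-plane diagonal 5.66 mm), a rigid
test–retest protocol, and paired method comparison.

A seedable synthetic spine phantom (geometric vertebrae with posterior
arches, ribs, pelvis, cord, liver, aorta; piecewise-constant PET with
planted Gaussian lesions) exercises every stage without patient data.

## Worked example

```bash
axskel run-all --out demo --seed 1
# -> 118 VOIs written to demo
```

This generates a phantom scan with one thoracic lesion, segments it
morphologically, builds the VOI inventory and classifies every VOI.
`demo/voi_manifest.csv` starts:

```
voi_id,kind,level,side,region,voxels
DVU_C1-C2,DVU,C1-C2,,cervical,176
DVU_C2-C3,DVU,C2-C3,,cervical,176
```

and `demo/detections.csv` contains one positive row — the DVU holding the
planted lesion:

```
   voi_id  suvmax background_region  suvmedian_bg  tbr  threshold
DVU_T6-T7    30.0          thoracic           6.0  5.0       2.25
```

The lesion (peak SUV 24 on a thoracic background of 6) gives SUVmax 30,
so TBR = 30/6 = 5.0 ≥ 2.25 → positive; all 117 lesion-free VOIs sit at
TBR 1.0 and stay negative. `joint_centers.csv` lists the 92 posterior
joint-center points with voxel indices and mm coordinates.

Other subcommands: `axskel phantom`, `segment-morph`, `build-atlases`,
`segment-atlas`, `validate`, `detect` (see `--help`).

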