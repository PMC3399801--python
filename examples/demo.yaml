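# End-to-end synthetic demonstration: three phantom "taxa" in distinct
# locomotor groups, 10 specimens each.  Run with:
#   trabkit all --config examples/demo.yaml
seed: 7
out_dir: trabkit_demo_out
shape: 64            # voxels per axis of each synthetic scan
voxel_mm: 0.03
blur_sigma_mm: 0.015 # scanner point-spread emulation
noise_sd: 8          # additive grayscale noise (60/190 plateaus)
stepwise: false
priors: equal
taxa:
  - name: platemorph
    group: biped
    n_specimens: 10
    body_mass_kg: 60
    phantom: {kind: plates, plate_thickness_mm: 0.18, plate_spacing_mm: 0.55}
  - name: rodmorph
    group: arboreal quad
    n_specimens: 10
    body_mass_kg: 5
    phantom: {kind: rods, rod_radius_mm: 0.12, pitch_mm: 0.6}
  - name: isomorph
    group: brachiator
    n_specimens: 10
    body_mass_kg: 11
    phantom: {kind: isotropic, target_bvtv: 0.35, correlation_length_mm: 0.3}
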