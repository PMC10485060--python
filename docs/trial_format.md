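# Trial directory format

One directory per treadmill trial:

| file | contents |
|---|---|
| `meta.yaml` | `schema_version` (major version 1), `subject_id`, `subject_mass` (kg), `belt_speed_nominal` (m/s), `belt_scale`, `kinematic_rate` (Hz), `grf_rate` (Hz) |
| `kinematics.tsv` | tab-separated, one row per kinematic sample |
| `grf.tsv` | tab-separated, one row per force-plate sample |
| `ground_truth.json` | optional sidecar written by the synthetic generator |

## `kinematics.tsv` columns

| column | units | convention |
|---|---|---|
| `time` | s | sample time |
| `heel_x_L`, `heel_x_R` | m | heel-marker X (travel direction), treadmill frame |
| `toe_x_L`, `toe_x_R` | m | toe-marker X |
| `com_x`, `com_y` | m | centre-of-mass X (travel) and Y (vertical) |
| `hip_angle_L`, `hip_angle_R` | rad | hip flexion-extension angle, **extension positive** |
| `hip_torque_L`, `hip_torque_R` | N·m | hip flexion-extension torque, **flexion positive** |

## `grf.tsv` columns

| column | units | convention |
|---|---|---|
| `time` | s | sample time |
| `grf_x_L`, `grf_x_R` | N | anterior (travel-direction) GRF component, one plate per side |
| `grf_y_L`, `grf_y_R` | N | vertical GRF component, ≥ 0 within noise |

A real recording (e.g. exported from a C3D file) can be analyzed by mapping
its marker/analog labels onto this layout; hip torques are consumed as a
provided channel (no inverse dynamics is performed).
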