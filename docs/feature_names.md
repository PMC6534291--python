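# Feature name registry

Each image yields 66 statistics, named `<dimension>_<statistic>`:
dimension `components` (H0) or `holes` (H1); statistics `count`,
`avg_lifetime`, `apf_area`, then for each summary polygon
(`landscape1..3`, `peel99`, `peel95`, `peel90`) the five descriptors
`Cx`, `Cy`, `A`, `P`, `F`. Order is dimension-major, statistic-minor.

## Display-name mapping for the published variable sets

| Display name                          | Identifier               | svm1 | svm2 |
| ------------------------------------- | ------------------------ | :--: | :--: |
| Number of Components                  | `components_count`       |  x   |  x   |
| Components 90% Convex Peel C_x        | `components_peel90_Cx`   |  x   |  x   |
| Components 90% Convex Peel P          | `components_peel90_P`    |  x   |      |
| Components 3rd Landscape A            | `components_landscape3_A`|      |  x   |
| Components 3rd Landscape F            | `components_landscape3_F`|  x   |      |
| Components Accumulative Persistence A | `components_apf_area`    |  x   |  x   |
| Holes 99% Convex Peel C_y             | `holes_peel99_Cy`        |  x   |  x   |
| Holes 1st Landscape P                 | `holes_landscape1_P`     |  x   |  x   |
| Holes 2nd Landscape C_y               | `holes_landscape2_Cy`    |  x   |      |
| Holes 3rd Landscape C_y               | `holes_landscape3_Cy`    |  x   |      |

`MODEL_FEATURE_SETS` in `fundustda.features` encodes these sets
programmatically (`"svm1"`: 9 variables, `"svm2"`: 6, `"all66"`: all).
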