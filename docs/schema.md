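# File formats and schemas

All files are delimited text (comma by default; tab inferred for `.tsv`),
header row mandatory, decimal points only.

## Measurement table (long format, canonical)

One row per (subject, variable).

| column           | type    | notes                                          |
|------------------|---------|------------------------------------------------|
| `subject_id`     | string  | opaque; unique per variable across the study   |
| `center_id`      | string  | opaque; never missing                          |
| `variable`       | string  | measurement name, e.g. `sitting_height`        |
| `value`          | float   | measurement units; may be missing; malformed cells become missing (logged) |
| `download_index` | int ≥ 0 | entry download; optional on read (defaults 0)  |
| `arm`            | string  | optional; `intervention` or `control`          |

A snapshot at download *d* is cumulative: it contains every row with
`download_index <= d`.

## Measurement table (wide convenience format)

Columns `subject_id, center_id[, download_index]` plus one column per
variable; melted to the long form on read.

## Arm assignment file

Two columns: `center_id, arm` with arm in {`intervention`, `control`}.

## Monitoring config (YAML or JSON)

Keys of `MonitoringConfig`:

- `variables`: list of variable names (required, non-empty)
- `icc_flag_threshold`: float in (0,1), default 0.05
- `icc_jump_threshold`: float in (0,1), default 0.05
- `alpha`: confidence level complement, default 0.05
- `plausible_ranges`: map variable → [low, high] (closed interval)
- `min_offset`: map variable → units threshold for shift flags
- `robust_z`: scaled-MAD threshold, default 3.0
- `reference_variables`: list (automated instruments; exempt from HIGH_ICC)
- `ci_method`: `smith` (default) or `bootstrap`

Round-trips exactly: `from_file(to_file(cfg)) == cfg`.

## Simulation config (YAML or JSON)

Keys of `SimulationConfig`: `k`, `center_sizes` (int or list), `mu`,
`sigma_b`, `sigma_w`, `variable`, `offsets` (map center → units),
`arm_assignment` (map center → arm), `arm_effect`, `downloads` (fractions
summing to 1), `center_schedules` (map center → fractions), `seed`.

## Correction rules file (JSON or YAML list)

Each entry: `center_id`, `variable`, `offset` (added to values; finite,
nonzero), optional `download_min`, `download_max`, `subject_ids` (list),
`reason`. For the `monitor` subcommand an entry may also carry
`after_download` (int): the rule is applied to every snapshot strictly
after that download.

## Monitoring report (`report.tsv`)

One row per (variable, download): `variable, download_index, rho, ci_low,
ci_high, se, n, k, flags`. Gap downloads have empty statistics. `flags`
joins triggered flag types with `;` (`TYPExN` when a type fired N times).

## Flag table (`flags.tsv`)

`download_index, variable, flag_type, details` with `flag_type` in
{`HIGH_ICC`, `ICC_JUMP`, `SHIFTED_CENTER`, `IMPLAUSIBLE_VALUE`} and
`details` a `key=value; ...` rendering.

## Structured report (`report.json`)

Object with keys `history` (variable → list of ICC estimates with fields
`variable, download_index, rho, rho_raw, se, ci_low, ci_high, alpha, k,
N`), `gaps` (variable → list of downloads), and `flags` (list of flag
objects with full-precision details). Keys sorted; serialization is
byte-deterministic.

## Change log (`--log` of `correct`, TSV)

`subject_id, center_id, variable, download_index, old_value, new_value,
offset, reason` — one row per modified value; `old_value` supports
bit-exact reversal.
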