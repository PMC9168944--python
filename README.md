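# rehabcompass

A library and CLI for digital post-stroke follow-up based on patient-reported
outcome measures (PROMs). It scores six instruments at item level — SIS 3.0
(plus additional SIS+ questions), HADS, FAS, smRSq, EQ-5D-3L and EAT-10 —
normalizes every domain onto a common 0–100 best-health scale, assembles the
seven-area "compass" graph (life, cognition, emotion, fatigue, sexuality and
continence, sensory function, motor function) with triage color bands and a
minimum-value inner marker, compares snapshots across follow-ups, and
summarizes unmet rehabilitation needs at cohort level (median, 25–75% IQR,
impairment frequency).

Key conventions:

- **Normalization.** Every domain is linearly rescaled to 0–100 with
  100 = best condition, regardless of the instrument's native direction.
- **Color bands.** red = [0, 30], orange = (30, 70), green = [70, 100];
  missing renders neutral grey.
- **Impairment.** A scored domain with a normalized value below 100 counts
  as impaired (threshold configurable).
- **Areas.** Each compass area is the equal-weight mean of its non-missing
  member domains; the inner marker shows the band of the lowest member.
  The default domain→area mapping is a documented reconstruction and lives
  in a config file (`src/rehabcompass/data/area_mapping.yaml`), not code.
- Instrument item banks are declarative YAML
  (`src/rehabcompass/data/instruments/*.yaml`) with placeholder prompts;
  deployments can override both item banks and mapping.

## CLI

All commands live under a single `rehabcompass` entry point
(equivalently `python -m rehabcompass.cli`):

```sh
# synthesize a 24-respondent cohort (profile YAML optional, seeded)
rehabcompass simulate --profile profile.yaml --seed 1 --out responses.csv

# validate + score into normalized 0-100 domain scores
rehabcompass score --responses responses.csv --out scores.csv

# one respondent's compass snapshot as JSON
rehabcompass compass --responses responses.csv --respondent r01 \
    --timepoint 12-month --out snapshot.json

# longitudinal delta between two follow-ups
rehabcompass compare --responses responses.csv --respondent r01 \
    --from-timepoint 3-month --to-timepoint 12-month --out delta.json

# cohort summary: median, IQR, impairment counts/frequencies
rehabcompass cohort --responses responses.csv --timepoint 12-month \
    --out summary.csv

# render: compass graph, per-area domain bars, or the group chart
rehabcompass render --responses responses.csv --respondent r01 \
    --timepoint 12-month --kind compass --out compass.svg
rehabcompass render --responses responses.csv --timepoint 12-month \
    --kind group --out group.svg --format svg
```

Exit codes: 0 success, 1 data-validation failure (machine-readable JSON
error on stderr), 2 usage error. SVG output is canonical and deterministic
(byte-identical for identical inputs); PNG is a derived raster.

Response input is long-format CSV with header
`respondent_id,timepoint,instrument_id,item_id,value` (blank value =
explicit missing) or equivalent JSON.

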