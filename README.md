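# csakit

Composite-spectra deconvolution and spectral-library annotation for
untargeted LC/HRMS metabolomics, built around MS1-only data.

Many LC/HRMS peaks never receive MS2 fragmentation, so they cannot be
annotated by conventional MS/MS library search. A single compound,
however, emits several co-eluting MS1 ions (adducts, in-source fragments,
isotopologues). `csakit`:

1. **Deconvolutes** co-eluting, intensity-correlated MS1 peaks into
   *composite spectra*: the most intense unassigned peak above an S/N
   threshold seeds a cluster; peaks within a retention-time window are
   recruited when their LOESS-smoothed, spline-interpolated extracted-ion
   chromatograms correlate with the seed's (Pearson r ≥ 0.98 by default,
   computed above a height fraction of each profile's own apex); clusters
   must have ≥ 2 ions spanning > 8 Da of ¹²C m/z, suppressing bare
   isotopic envelopes. ¹³C partners are appended only when their ¹²C
   counterpart is a member.
2. **Extracts DDA spectra** (three same-precursor consolidation options:
   integrate all scans, keep the most abundant, or denoise by RSD-flatness
   plus precursor-profile correlation) and **DIA spectra** (fragments from
   the apex-nearest MS2 scan, retained when their MS2-channel EIC
   correlates with the precursor's MS1 EIC).
3. **Aggregates** spectra recurring across files into unique variants
   (RT window + entropy-similarity gate) with detection frequencies, and
   builds batch-consensus spectra via Tanimoto merging on aligned-table
   row sets.
4. **Searches** spectra against MSP/MGF libraries converted to a
   fragmentation-spectra database (FSDB) with pre-computed spectral
   entropy and characteristic markers: cosine similarity over matched
   fragment pairs, entropy similarity of the 1:1 merged
   (weight-transformed) spectra, normalized Euclidean mass error (NEME),
   final score `cosine × entropy_similarity²`, and study-level
   frequency/median-rank summaries.

A synthetic-fixture module generates ground-truthed mzML scan data, peak
lists, aligned tables and libraries, so everything builds and tests
without downloads.

## Command line

Three entry points: `csa`, `fsa`, `fixtures`.

```bash
# make a synthetic dataset to play with
fixtures generate --preset csa --out-dir demo --seed 1

# deconvolute one file into composite spectra (MSP output)
csa deconvolute --scans demo/csa_fixture.mzML --peaks demo/csa_fixture.tsv \
    --out-dir demo/out

# collapse recurring spectra across files into variants
csa aggregate --input-msp demo/out/csa_fixture_CSA.msp --out-dir demo/agg

# build a searchable database from a spectral library and search it
fsa build-db --library demo/csa_library.msp --out demo/lib.fsdb.json --out-dir demo
fsa search --query demo/out/csa_fixture_CSA.msp --db demo/lib.fsdb.json \
    --out-dir demo/hits

# summarize per-sample hit tables across a study
fsa summarize --results demo/hits/csa_fixture_CSA_hits.tsv --out-dir demo
```

`csa dda` / `csa dia` share the `deconvolute` flag set. Every command
accepts `--config params.yml` (YAML; sections `csa`, `dda`, `dia`,
`search`, `aggregate`, plus `io`, `threads`, `seed`; unknown keys and
out-of-range values are rejected by name), `--threads`, `--seed` and
`--log-level`. Each run writes a `manifest.json` with the full parameter
snapshot and a config hash for reproducibility.

## Input formats

* **Scans**: centroided mzML (profile data rejected with a message);
  32/64-bit float arrays, optional zlib compression; RT normalized to
  minutes.
* **Peak lists**: TSV/CSV with columns
  `peak_id, mz, mz_13C, rt_apex, rt_start, rt_end, height, snr`
  (`peak_id`, `mz_13C` optional) — the schema produced by an upstream
  MS1 peak picker.
* **Aligned tables**: TSV/CSV with `mz`, `rt` plus one height column per
  sample (0/blank = not detected).
* **Spectral libraries**: NIST-style MSP (read/write) and MGF (read),
  selected by extension.
* **FSDB**: this package's versioned JSON container
  (schema `csakit-fsdb-1`): flat m/z and intensity arrays with per-entry
  offsets, cached entropy and marker arrays, build-parameter snapshot.
  Building twice from the same inputs is byte-identical.

## Package layout

| module | role |
| --- | --- |
| `csakit.spectra` | `FragmentSpectrum` core type |
| `csakit.spectra_io` | MSP/MGF I/O, FSDB build/save/load |
| `csakit.mzml` | minimal mzML reader/writer |
| `csakit.ms1` | scan model, peak lists, EIC extraction, LOESS smoothing |
| `csakit.deconv` | composite-spectra deconvolution |
| `csakit.ddia` | DDA consolidation and DIA extraction |
| `csakit.aggregate` | variant aggregation, Tanimoto consensus |
| `csakit.fsa` | similarity scoring, prefiltering, search, study summary |
| `csakit.synth` | ground-truthed synthetic fixtures |
| `csakit.config` / `csakit.workflow` / `csakit.cli` | YAML config, dispatch, CLI |
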