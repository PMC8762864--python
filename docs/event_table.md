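# Event-table dialect

The textual interchange format for signal-aligned reads (the conceptual
output of a re-squiggle step).  Tab-separated, UTF-8, one header line,
then one row per (read, reference position).

| column | type | constraints | description |
|---|---|---|---|
| `read_id` | string | non-empty | read identifier; pooling prefixes `replicate:` |
| `transcript_id` | string | non-empty | reference transcript the read aligns to |
| `position` | int | ≥ 0; contiguous per read | 0-based transcript coordinate |
| `event_mean` | float | — | mean current of the event, pA |
| `event_median` | float | — | median current, pA |
| `event_sd` | float | ≥ 0 (non-gap) | current standard deviation, pA |
| `dwell` | float | > 0 (non-gap) | dwell time, arbitrary units |
| `base_quality` | float | — | Phred-like base quality |
| `match_flag` | enum | `match` / `mismatch` / `gap` | basecall vs reference |

Rules:

* each read's rows cover one contiguous half-open interval of transcript
  positions (its span); a punctured span is a parse error;
* `gap` rows mark reference positions deleted in the basecall; they
  carry no signal (all numeric feature columns written as 0) and are
  excluded from feature windows, but count as basecall errors for
  mismatch labeling;
* insertions relative to the reference have no rows;
* parsers reject non-numeric fields, negative `event_sd` and
  non-positive `dwell` at non-gap positions, reporting the line number.

A machine-readable column list is available as
`m6acall.event_io.EVENT_COLUMNS`.  Adapters from signal archives
(e.g. fast5/HDF5) are an extension point: anything that can emit this
table can feed the pipeline.
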