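# racemap

Maps the templated 3′-end coordinates of a single transcript's isoforms
from RNA ligase-mediated 3′-RACE deep-sequencing reads, and quantifies
gel time-courses of their decay.

Human telomerase RNA (hTR) is transcribed as a 3′-extended precursor and
processed to a 451-nt mature form. In 3′-RACE sequencing, a constant
linker is ligated to every RNA 3′ end, so the read sequence crosses the
exact terminus: everything 5′ of the linker is the insert — a templated
suffix of the transcript plus any non-templated nucleotide additions
(NTNA, typically oligo-A). `racemap` turns such libraries into per-sample
3′-end distributions and isoform-class fractions, and compares a
knockdown against a control. A full synthetic-library simulator with
ground truth makes every stage testable without any sequencing download.

## Method

For a read insert \(r\) of length \(n\), the end-mapper searches tail
trims \(t = 0, 1, 2, \dots\); at each \(t\) the anchor
\(a = r[n-t-20 \,..\, n-t]\) is slid over the reference, a placement
ending at coordinate \(e\) being valid when the two most-3′ anchor bases
match exactly and the remaining 18 carry at most 2 substitutions. The
call is made at the smallest \(t\) with any valid placement: the end
coordinate is the most 3′ valid \(e\) inside the assignment window
(hTR coordinates 366–641), and the \(t\) trimmed bases are reported as
the NTNA. Inserts shorter than 20 nt are rejected (`short_match`), reads
whose only placements fall outside the window are `out_of_window`, and
a read requires a 10-nt exact match to the linker at all. Ends are
classified mature (451), exS (452–460), exL (>460) or sub-mature
(<451). PCR duplicates are collapsed on the (10-nt molecular barcode,
insert) key before tallying; every assigned read counts once,
with or without an NTNA.

For gel densitometry, band intensities are normalized per lane to a
loading control and then to time zero,
\(s(t) = \frac{I_{sp}(t)/I_{ctl}(t)}{I_{sp}(0)/I_{ctl}(0)}\); the
50%-decay time is read off by log-linear interpolation, and fold changes
between conditions are tested with a two-sided Student's t-test.

## Worked example

`python examples/simulate_and_map.py` simulates 5,000 molecules (55%
mature, 25% exS, 15% exL, 5% sub-mature; oligo-A tails of mean length 5
on half of them; twofold PCR duplication; 0.1% substitution errors) and
runs the full pipeline:

```
simulated 5000 molecules -> 9977 reads
reads after dedup: 5032; assigned: 4960
failures: {'no_linker': 68, 'out_of_window': 4}
  sub_mature: 0.052
      mature: 0.554
         exS: 0.244
         exL: 0.149
fraction of assigned reads with a non-templated tail: 0.476
fraction with a pure oligo-A tail:                    0.472
```

Deduplication recovers almost exactly the 5,000 simulated molecules
(the surplus are reads whose linker match was destroyed by a
substitution error, leaving their duplicates uncollapsible), and the
recovered class fractions match the simulated mixture. The other
examples show a knockdown-versus-control comparison
(`examples/knockdown_comparison.py`: Δ(exL) = +0.237, Δ(exS) = −0.134
when exL mass is raised from 5% to 30%) and decay quantification
(`examples/decay_quantification.py`: recovers 22.4 min and 69.9 min
half-times from synthetic gels, fold change 2.03 ± 0.09,
p = 6.1 × 10⁻⁴).

A thin CLI wraps the same library: `racemap simulate`, `racemap run`,
`racemap summarize`, `racemap quantify` (see `racemap --help`).

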