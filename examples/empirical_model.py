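"""Build an empirical kmer model from nanopolish eventalign output.

Writes a small synthetic eventalign table (the format nanopolish emits),
then averages the measured event levels per kmer — the same procedure used
to build reference RNA models from sequencing runs.
"""

import tempfile
from pathlib import Path

import numpy as np

import poregraph as pg
from poregraph.io import EventalignStats

rng = np.random.default_rng(0)
header = ("contig\tposition\treference_kmer\tread_index\tstrand\tevent_index\t"
          "event_level_mean\tevent_stdv\tevent_length\tmodel_kmer\tmodel_mean\t"
          "model_stdv")
true_levels = {"AACGU": 85.0, "ACGUA": 102.0, "CGUAC": 118.0}
rows = []
for i in range(300):
    if i % 40 == 7:
        km, level = "NNNNN", 0.0  # unalignable event placeholder
    else:
        km = list(true_levels)[i % 3]
        level = true_levels[km] + rng.normal(0, 2.0)
    rows.append(f"chr\t{i}\t{km}\t0\tt\t{i}\t{level:.3f}\t1.2\t0.004\t{km}\t{level:.3f}\t1.0")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "eventalign.tsv"
    path.write_text("\n".join([header] + rows) + "\n")
    stats = EventalignStats()
    model, counts = pg.empirical_model_from_events(
        pg.read_eventalign(path, stats), nucleic_type="RNA", min_count=2
    )

print(f"rows parsed: {stats.n_records}, placeholder rows skipped: "
      f"{stats.n_skipped_placeholder}")
for km in sorted(model.levels):
    print(f"  {km}: mean {model[km]:7.2f} pA over {counts[km]} events "
          f"(true {true_levels[km]:.1f})")

# Each kmer's level is the plain average of all its recorded events; with
# enough coverage the empirical means converge on the true characteristic
# currents, giving a reference model without any vendor table.
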