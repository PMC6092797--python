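"""Shared locations and the simulation scale used by the analysis scripts.

Simulated raw data (FASTA/GTF/BED, tens of MB) lives under scratch/; the
small result tables every later script writes live under results/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "simdata"
RESULTS = ROOT / "results"

N_GENES = 96
SEED = 1
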