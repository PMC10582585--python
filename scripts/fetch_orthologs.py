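#!/usr/bin/env python
"""Optional helper: download reference human orthologs and check their calls.

Requires network access (the core pipeline never downloads; it consumes
local files only).  Fetches the human FOXP2 (UniProt O15409) and FOXP1
(UniProt Q9H334) protein sequences and verifies the expected repeat calls:
FOXP2 Q1 = 40, Q2 = 10 (ratio 4.0); FOXP1 Q1 = 6, Q2 = 7.

Usage:
    python scripts/fetch_orthologs.py [--out-dir DIR]
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

from polyqvoc.io import read_fasta
from polyqvoc.repeats import HingeConfig, call_repeats

ACCESSIONS = {
    # accession: (gene, expected_q1, expected_q2)
    "O15409": ("FOXP2", 40, 10),
    "Q9H334": ("FOXP1", 6, 7),
}

URL = "https://rest.uniprot.org/uniprotkb/{accession}.fasta"


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out-dir", default="scratch/orthologs")
    args = parser.parse_args()
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    failures = 0
    for accession, (gene, exp_q1, exp_q2) in ACCESSIONS.items():
        url = URL.format(accession=accession)
        try:
            with urllib.request.urlopen(url, timeout=30) as response:
                text = response.read().decode()
        except OSError as exc:
            print(f"{accession}: download failed ({exc}); is the network up?")
            return 2
        (out / f"{accession}.fasta").write_text(text)
        record = read_fasta(text, gene)[0]
        call = call_repeats(record.sequence, HingeConfig(gene=gene))
        ok = call.q1_len == exp_q1 and call.q2_len == exp_q2
        status = "OK" if ok else "MISMATCH"
        print(
            f"{accession} ({gene}): Q1={call.q1_len} Q2={call.q2_len} "
            f"ratio={call.ratio_r:.4f} expected Q1={exp_q1} Q2={exp_q2} -> {status}"
        )
        failures += 0 if ok else 1
    return 1 if failures else 0


if __name__ == "__main__":
    sys.exit(main())
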