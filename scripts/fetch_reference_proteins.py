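#!/usr/bin/env python
"""Fetch the UniProtKB sequences behind the reported worked assignments.

Downloads the sequences of every accession in
``icmaldi.reported_assignments.REPORTED_ASSIGNMENTS`` from the UniProt
REST API and writes them to ``data/uniprot_reference.fasta``.  Network
access to rest.uniprot.org is required; UniProt data are not
redistributed with this package.

Usage:
    python scripts/fetch_reference_proteins.py [-o data/uniprot_reference.fasta]
"""

from __future__ import annotations

import argparse
import sys
import urllib.error
import urllib.request
from pathlib import Path

from icmaldi.reported_assignments import REPORTED_ASSIGNMENTS

API = "https://rest.uniprot.org/uniprotkb/search?query={}&format=fasta&size=1"


def fetch(accession: str) -> str:
    # entry names (e.g. PSBT_SYNR3) need an id: query; plain accessions work directly
    url = API.format(f"id:{accession}" if "_" in accession else accession)
    with urllib.request.urlopen(url, timeout=30) as resp:
        return resp.read().decode()


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "-o", "--output",
        default=Path(__file__).resolve().parent.parent / "data" / "uniprot_reference.fasta",
        type=Path,
    )
    args = parser.parse_args()

    accessions = sorted({a.accession for a in REPORTED_ASSIGNMENTS})
    chunks = []
    for acc in accessions:
        try:
            fasta = fetch(acc)
        except (urllib.error.URLError, OSError) as exc:
            print(f"failed to fetch {acc}: {exc}", file=sys.stderr)
            continue
        if fasta.startswith(">"):
            chunks.append(fasta.rstrip() + "\n")
            print(f"fetched {acc}")
        else:
            print(f"no record for {acc}", file=sys.stderr)

    if not chunks:
        print("no sequences fetched; is rest.uniprot.org reachable?", file=sys.stderr)
        sys.exit(1)
    args.output.parent.mkdir(parents=True, exist_ok=True)
    args.output.write_text("".join(chunks))
    print(f"wrote {len(chunks)} records to {args.output}")


if __name__ == "__main__":
    main()
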