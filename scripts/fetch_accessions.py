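#!/usr/bin/env python
"""Download deposited Amaryllidaceae plastome accessions from NCBI.

Optional helper: nothing in the library depends on it. Fetches annotated
GenBank flat files into data/accessions/ so the deposited-accession checks
in tests/test_acceptance.py can run. Requires network access.

Usage:
    python scripts/fetch_accessions.py [ACCESSION ...]
"""

from __future__ import annotations

import sys
import time
import urllib.parse
import urllib.request
from pathlib import Path

EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
DEFAULT = [
    "MN539611", "MN539612", "MN539613", "MN539614", "MN539615",
]
OUT_DIR = Path(__file__).resolve().parent.parent / "data" / "accessions"


def fetch(accession: str) -> Path:
    params = urllib.parse.urlencode(
        {"db": "nuccore", "id": accession, "rettype": "gbwithparts", "retmode": "text"}
    )
    out = OUT_DIR / f"{accession}.gb"
    with urllib.request.urlopen(f"{EFETCH}?{params}", timeout=60) as resp:
        text = resp.read().decode()
    if not text.startswith("LOCUS"):
        raise RuntimeError(f"{accession}: unexpected response from NCBI")
    out.write_text(text)
    return out


def main() -> None:
    accessions = sys.argv[1:] or DEFAULT
    OUT_DIR.mkdir(parents=True, exist_ok=True)
    for acc in accessions:
        path = fetch(acc)
        print(f"{acc} -> {path} ({path.stat().st_size:,} bytes)")
        time.sleep(0.4)  # NCBI rate-limit courtesy


if __name__ == "__main__":
    main()
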