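#!/usr/bin/env python
"""Download the pinned reference assembly (GCF_000007005.1 / NC_002754.1)
into data/reference/ as uncompressed text.

Needs ordinary internet access to the NCBI FTP mirror; run once on a
networked machine.  The genome-content acceptance test and the t1-t5
entries of scripts/acceptance.py activate automatically when these files
are present.
"""

import gzip
import sys
import urllib.request
from pathlib import Path

BASE = (
    "https://ftp.ncbi.nlm.nih.gov/genomes/all/GCF/000/007/005/"
    "GCF_000007005.1_ASM700v1/"
)
FILES = [
    "GCF_000007005.1_ASM700v1_genomic.fna.gz",
    "GCF_000007005.1_ASM700v1_genomic.gff.gz",
]


def main() -> int:
    out_dir = Path(__file__).resolve().parent.parent / "data" / "reference"
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in FILES:
        target = out_dir / name[: -len(".gz")]
        if target.exists():
            print(f"already present: {target}")
            continue
        url = BASE + name
        print(f"fetching {url}")
        with urllib.request.urlopen(url) as response:
            data = gzip.decompress(response.read())
        target.write_bytes(data)
        print(f"wrote {target} ({len(data):,} bytes)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
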