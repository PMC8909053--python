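"""The focused shRNA library manifest: shRNA → gene map with control roles.

The library emulated by default mirrors a focused epigenetics library used
for dropout screening in primary AML samples: 540 genes at 12 shRNAs per
gene (6480 shRNAs), of which five genes are common-essential positive
controls (proteasome and ribosome subunits *PSMA1*, *PSMA3*, *RPS13*,
*RPL6*, *RPL30*) and one is a non-targeting negative control (*LUC*,
anti-luciferase).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import InvalidManifestError

ROLE_TARGET = "target"
ROLE_POSITIVE = "positive_control"
ROLE_NEGATIVE = "negative_control"
ROLES = (ROLE_TARGET, ROLE_POSITIVE, ROLE_NEGATIVE)

POSITIVE_CONTROL_GENES = ("PSMA1", "PSMA3", "RPS13", "RPL6", "RPL30")
NEGATIVE_CONTROL_GENE = "LUC"

_BARCODE_RE = re.compile(r"^[ACGT]+$")

MANIFEST_COLUMNS = ["shrna_id", "gene", "role", "barcode"]


@dataclass(frozen=True)
class LibraryManifest:
    """Immutable view of a pooled shRNA library.

    Parameters
    ----------
    entries
        One row per shRNA with columns ``shrna_id``, ``gene``, ``role`` and
        optionally ``barcode`` (fixed-length nucleotide tag, unique per
        shRNA). Row order defines the canonical shRNA order used by count
        tables downstream.
    """

    entries: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.entries
        required = {"shrna_id", "gene", "role"}
        missing = required - set(df.columns)
        if missing:
            raise InvalidManifestError(f"manifest missing columns: {sorted(missing)}")
        if df["shrna_id"].duplicated().any():
            dups = df.loc[df["shrna_id"].duplicated(), "shrna_id"].tolist()
            raise InvalidManifestError(f"duplicate shrna_id values: {dups[:5]}")
        bad_roles = set(df["role"]) - set(ROLES)
        if bad_roles:
            raise InvalidManifestError(f"unknown roles: {sorted(bad_roles)}")
        roles_per_gene = df.groupby("gene", sort=False)["role"].nunique()
        if (roles_per_gene > 1).any():
            offenders = roles_per_gene[roles_per_gene > 1].index.tolist()
            raise InvalidManifestError(f"role not constant within gene: {offenders}")
        if "barcode" in df.columns and df["barcode"].notna().any():
            bcs = df["barcode"].dropna()
            if len(bcs) != len(df):
                raise InvalidManifestError("barcodes must be present for all shRNAs or none")
            if bcs.duplicated().any():
                raise InvalidManifestError("barcodes are not unique")
            lengths = bcs.str.len().unique()
            if len(lengths) != 1:
                raise InvalidManifestError(f"heterogeneous barcode lengths: {sorted(lengths)}")
            if not bcs.map(lambda b: bool(_BARCODE_RE.match(b))).all():
                raise InvalidManifestError("barcodes must be over the alphabet {A,C,G,T}")
        object.__setattr__(self, "entries", df.reset_index(drop=True))

    # -- basic accessors ---------------------------------------------------

    @property
    def shrna_ids(self) -> pd.Index:
        return pd.Index(self.entries["shrna_id"])

    @property
    def genes(self) -> list[str]:
        """Unique gene symbols in manifest order."""
        return list(dict.fromkeys(self.entries["gene"]))

    @property
    def n_shrnas(self) -> int:
        return len(self.entries)

    @property
    def n_genes(self) -> int:
        return self.entries["gene"].nunique()

    @property
    def gene_of(self) -> pd.Series:
        """shrna_id → gene symbol."""
        return self.entries.set_index("shrna_id")["gene"]

    @property
    def gene_roles(self) -> pd.Series:
        """gene → role (roles are constant within a gene)."""
        return self.entries.drop_duplicates("gene").set_index("gene")["role"]

    @property
    def positive_controls(self) -> list[str]:
        roles = self.gene_roles
        return list(roles.index[roles == ROLE_POSITIVE])

    @property
    def negative_controls(self) -> list[str]:
        roles = self.gene_roles
        return list(roles.index[roles == ROLE_NEGATIVE])

    @property
    def has_barcodes(self) -> bool:
        return "barcode" in self.entries.columns and self.entries["barcode"].notna().all()

    @property
    def barcode_length(self) -> int:
        if not self.has_barcodes:
            raise InvalidManifestError("manifest has no barcodes")
        return len(self.entries["barcode"].iloc[0])

    def shrnas_of(self, gene: str) -> list[str]:
        sel = self.entries.loc[self.entries["gene"] == gene, "shrna_id"]
        if sel.empty:
            from .errors import UnknownGeneError

            raise UnknownGeneError(gene)
        return list(sel)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path) -> None:
        df = self.entries.copy()
        if "barcode" not in df.columns:
            df["barcode"] = pd.NA
        df[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "LibraryManifest":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if "barcode" in df.columns and df["barcode"].isna().all():
            df = df.drop(columns=["barcode"])
        return cls(df)
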