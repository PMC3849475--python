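"""Shared fixtures: tiny constructed drug collections and oracles."""

from __future__ import annotations

import io as stdio

import pytest

from illicitnet import DrugRecord, GeneTarget, TargetRef


def make_drug(
    drug_id: str,
    name: str = "",
    groups=("approved",),
    targets=(),
    atc_codes=(),
    categories=(),
) -> DrugRecord:
    """Terse DrugRecord factory; ``targets`` are human accession strings."""
    return DrugRecord(
        drug_id=drug_id,
        name=name or drug_id.lower(),
        groups=frozenset(groups),
        categories=frozenset(categories),
        atc_codes=tuple(atc_codes),
        target_refs=tuple(TargetRef(acc, "Humans") for acc in targets),
    )


THREE_DRUG_XML = """<?xml version="1.0" encoding="UTF-8"?>
<drugbank>
  <drug>
    <drugbank-id>DB00001</drugbank-id>
    <name>alphadrug</name>
    <groups><group>Approved</group><group>Illicit</group></groups>
    <categories><category>Hypnotics and Sedatives</category></categories>
    <atc-codes><atc-code code="N05BA01"/></atc-codes>
    <targets>
      <target><polypeptide uniprot-id="P11111" species="Humans"/></target>
      <target><polypeptide uniprot-id="P22222" species="Humans"/></target>
    </targets>
  </drug>
  <drug>
    <drugbank-id>DB00002</drugbank-id>
    <name>betadrug</name>
    <groups><group>approved</group></groups>
    <categories/>
    <atc-codes/>
    <targets>
      <target><polypeptide uniprot-id="P22222" species="Humans"/></target>
      <target><polypeptide uniprot-id="P33333" species="Rats"/></target>
    </targets>
  </drug>
  <drug>
    <drugbank-id>DB00003</drugbank-id>
    <name>gammadrug</name>
    <groups><group>experimental</group></groups>
  </drug>
</drugbank>
"""


@pytest.fixture
def three_drug_xml() -> stdio.BytesIO:
    return stdio.BytesIO(THREE_DRUG_XML.encode())


@pytest.fixture
def small_mapping() -> dict[str, GeneTarget]:
    return {
        "P11111": GeneTarget("P11111", "GABRA1", 2554),
        "P22222": GeneTarget("P22222", "OPRM1", 4988),
        "P33333": GeneTarget("P33333", "SLC6A3", 6531),
        "P44444": GeneTarget("P44444", "ESR1", 2099),
        "P55555": GeneTarget("P55555", "DRD2", 1813),
    }


@pytest.fixture
def five_drug_records() -> list[DrugRecord]:
    """Five drugs, two illicit; overlap structure used across tests."""
    return [
        make_drug("DB00001", groups=("approved", "illicit"), targets=("P11111", "P22222")),
        make_drug("DB00002", groups=("illicit",), targets=("P33333",)),
        make_drug("DB00003", targets=("P22222",)),  # related via OPRM1
        make_drug("DB00004", targets=("P44444",)),  # other
        make_drug("DB00005", targets=()),  # no targets at all
    ]
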