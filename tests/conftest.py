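from __future__ import annotations

import textwrap

import pytest

from metacure.correction import default_synonyms
from metacure.records import MetadataRecord
from metacure.templates import load_template


@pytest.fixture(scope="session")
def template():
    from metacure.cli import _data_path

    return load_template(_data_path("biosample_tissue.template.json"))


@pytest.fixture(scope="session")
def synonyms():
    return default_synonyms()


@pytest.fixture()
def small_corpus():
    def rec(i, tissue):
        return MetadataRecord(
            record_id=f"R{i}",
            source="synthetic",
            pairs=[("organism", "Homo sapiens"), ("tissue", tissue)],
        )

    return [
        rec(1, "lung"),
        rec(2, "lung cancer"),
        rec(3, " Lung"),
        rec(4, "whole blood"),
        rec(5, "kidney"),
    ]


BIOSAMPLE_XML = textwrap.dedent(
    """\
    <?xml version="1.0" encoding="UTF-8"?>
    <BioSampleSet>
      <BioSample accession="SAMN0001">
        <Attributes>
          <Attribute attribute_name="tissue" harmonized_name="tissue">lung cancer</Attribute>
          <Attribute attribute_name="organism" harmonized_name="organism">Homo sapiens</Attribute>
        </Attributes>
      </BioSample>
      <BioSample accession="SAMN0002">
        <Attributes>
          <Attribute display_name="tissue">whole blood</Attribute>
          <Attribute harmonized_name="age">54</Attribute>
        </Attributes>
      </BioSample>
      <BioSample accession="SAMN0003">
        <Attributes>
          <Attribute harmonized_name="tissue">ovarian tumor</Attribute>
        </Attributes>
      </BioSample>
    </BioSampleSet>
    """
)

BIOSAMPLE_XML_TRUNCATED = textwrap.dedent(
    """\
    <?xml version="1.0" encoding="UTF-8"?>
    <BioSampleSet>
      <BioSample accession="SAMN0001">
        <Attributes>
          <Attribute harmonized_name="tissue">lung</Attribute>
        </Attributes>
      </BioSample>
      <BioSample accession="SAMN0002">
        <Attributes>
          <Attribute harmonized_name="tissue">liver</Attribute>
        </Attributes>
      </BioSample>
      <BioSample accession="SAMN0003">
        <Attributes>
          <Attribute harmonized_name="tissue">blood
    """
)

GEO_SOFT = textwrap.dedent(
    """\
    ^SAMPLE = GSM100
    !Sample_title = NSCLC biopsy
    !Sample_characteristics_ch1 = tissue: NSCLC tumor
    !Sample_characteristics_ch1 = age: 64
    !Sample_characteristics_ch1 = sex: male
    !Sample_characteristics_ch1 = stage: IIIa
    !Sample_description = Tumor tissue resected from a patient with non-small cell lung cancer.
    ^SAMPLE = GSM101
    !Sample_characteristics_ch1 = tissue: whole blood
    !Sample_characteristics_ch1 = no colon here
    """
)


@pytest.fixture()
def biosample_xml_file(tmp_path):
    p = tmp_path / "biosamples.xml"
    p.write_text(BIOSAMPLE_XML)
    return p


@pytest.fixture()
def biosample_truncated_file(tmp_path):
    p = tmp_path / "biosamples_truncated.xml"
    p.write_text(BIOSAMPLE_XML_TRUNCATED)
    return p


@pytest.fixture()
def geo_soft_file(tmp_path):
    p = tmp_path / "samples.soft"
    p.write_text(GEO_SOFT)
    return p
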