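<?xml version="1.0" encoding="UTF-8"?>
<!-- Spatial Temporal Markup Language, Level 1 Version 1.
     Normative structure for pseudo-3D spatio-temporal time series files:
     an experiment is a non-empty list of timepoints, each holding spatial
     entities (regions/clusters with eleven spatial measures) and named
     numeric state variables. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="qualified">

  <xs:simpleType name="nonNegativeReal">
    <xs:restriction base="xs:decimal">
      <xs:minInclusive value="0"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="angleDegrees">
    <xs:restriction base="xs:decimal">
      <xs:minInclusive value="0"/>
      <xs:maxInclusive value="360"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="unitInterval">
    <xs:restriction base="xs:decimal">
      <xs:minInclusive value="0"/>
      <xs:maxInclusive value="1"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="shapeName">
    <xs:restriction base="xs:string">
      <xs:enumeration value="triangular"/>
      <xs:enumeration value="rectangular"/>
      <xs:enumeration value="circular"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="entityTypeName">
    <xs:restriction base="xs:string">
      <xs:enumeration value="region"/>
      <xs:enumeration value="cluster"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:complexType name="pseudo3DType">
    <xs:sequence>
      <xs:element name="clusteredness" type="nonNegativeReal"/>
      <xs:element name="density" type="nonNegativeReal"/>
      <xs:element name="area" type="nonNegativeReal"/>
      <xs:element name="perimeter" type="nonNegativeReal"/>
      <xs:element name="distanceFromOrigin" type="nonNegativeReal"/>
      <xs:element name="angle" type="angleDegrees"/>
      <xs:element name="triangularMeasure" type="unitInterval"/>
      <xs:element name="rectangularMeasure" type="unitInterval"/>
      <xs:element name="circularMeasure" type="unitInterval"/>
      <xs:element name="centroidX" type="nonNegativeReal"/>
      <xs:element name="centroidY" type="nonNegativeReal"/>
      <xs:element name="shape" type="shapeName" minOccurs="0"/>
    </xs:sequence>
    <xs:attribute name="type" type="entityTypeName" use="required"/>
  </xs:complexType>

  <xs:complexType name="spatialEntityType">
    <xs:sequence>
      <xs:element name="pseudo3D" type="pseudo3DType"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="numericStateVariableType">
    <xs:sequence>
      <xs:element name="name">
        <xs:simpleType>
          <xs:restriction base="xs:string">
            <xs:minLength value="1"/>
          </xs:restriction>
        </xs:simpleType>
      </xs:element>
      <xs:element name="value" type="xs:decimal"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="timepointType">
    <xs:sequence>
      <xs:element name="spatialEntity" type="spatialEntityType"
                  minOccurs="0" maxOccurs="unbounded"/>
      <xs:element name="numericStateVariable" type="numericStateVariableType"
                  minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
    <xs:attribute name="value" type="xs:nonNegativeInteger" use="optional"/>
  </xs:complexType>

  <xs:element name="experiment">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="timepoint" type="timepointType"
                    minOccurs="1" maxOccurs="unbounded"/>
      </xs:sequence>
      <xs:attribute name="stmlVersion" type="xs:string" use="optional" default="L1V1"/>
    </xs:complexType>
  </xs:element>

</xs:schema>
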