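# MUSC clinical-note schema. A guideline change over the life of the corpus
# merged some Street/City annotations into "StreetCity" and some
# State/Country annotations into "StateCountry"; both merged labels are kept
# as their own tier-2 values because they cannot be split after the fact.
# All identifier types except social security numbers are grouped as
# "Other ID".

schema: musc
dialect: inline_xml

[Patient]
locator: PATIENT
tier0: PII
tier1: Names
tier2: Patient

[Provider]
locator: PROVIDER
tier0: PII
tier1: Names
tier2: Provider

[Relative]
locator: RELATIVE
tier0: PII
tier1: Names
tier2: Relative

[OtherPerson]
locator: OTHERPERSON
tier0: PII
tier1: Names
tier2: OtherPerson

[Profession]
locator: PROFESSION
tier0: PII
tier1: Occupations
tier2: Profession

[Hospital]
locator: HOSPITAL
tier0: PII
tier1: Address
tier2: Hospital

[Street]
locator: STREET
tier0: PII
tier1: Address
tier2: Street

[City]
locator: CITY
tier0: PII
tier1: Address
tier2: City

[StreetCity]
locator: STREETCITY
tier0: PII
tier1: Address
tier2: StreetCity

[State]
locator: STATE
tier0: PII
tier1: Address
tier2: State

[Country]
locator: COUNTRY
tier0: PII
tier1: Address
tier2: Country

[StateCountry]
locator: STATECOUNTRY
tier0: PII
tier1: Address
tier2: StateCountry

[Zip]
locator: ZIP
tier0: PII
tier1: Address
tier2: Zip

[OtherGeo]
locator: OTHERGEO
tier0: PII
tier1: Address
tier2: OtherGeo

[Age]
locator: AGE
tier0: PII
tier1: Age
tier2: Age

[Date]
locator: DATE
tier0: PII
tier1: Time
tier2: Date

[Phone]
locator: PHONE
tier0: PII
tier1: ContactInformation
tier2: Phone

[Fax]
locator: FAX
tier0: PII
tier1: ContactInformation
tier2: Fax

[Email]
locator: EMAIL
tier0: PII
tier1: ContactInformation
tier2: Email

[SSN]
locator: SSN
tier0: PII
tier1: Identifiers
tier2: SSN

[Other ID]
locator: OTHERID
tier0: PII
tier1: Identifiers
tier2: OtherID
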