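# Canonical PII tier taxonomy.
# Native names here ARE the tier-2 categories; tier 1 groups them into the
# seven semantic families and tier 0 collapses everything to PII. The
# synthetic corpus generator plants annotations in this schema, and it is the
# natural choice for both sides of a synthetic evaluation.

schema: tiers
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

[Username]
locator: USERNAME
tier0: PII
tier1: Names
tier2: Username

[Profession]
locator: PROFESSION
tier0: PII
tier1: Occupations
tier2: Profession

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

[Hospital]
locator: HOSPITAL
tier0: PII
tier1: Address
tier2: Hospital

[Organization]
locator: ORGANIZATION
tier0: PII
tier1: Address
tier2: Organization

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

[URL]
locator: URL
tier0: PII
tier1: ContactInformation
tier2: URL

[SSN]
locator: SSN
tier0: PII
tier1: Identifiers
tier2: SSN

[MedicalRecord]
locator: MEDICALRECORD
tier0: PII
tier1: Identifiers
tier2: MedicalRecord

[HealthPlan]
locator: HEALTHPLAN
tier0: PII
tier1: Identifiers
tier2: HealthPlan

[Account]
locator: ACCOUNT
tier0: PII
tier1: Identifiers
tier2: Account

[License]
locator: LICENSE
tier0: PII
tier1: Identifiers
tier2: License

[Vehicle]
locator: VEHICLE
tier0: PII
tier1: Identifiers
tier2: Vehicle

[Device]
locator: DEVICE
tier0: PII
tier1: Identifiers
tier2: Device

[BiometricID]
locator: BIOID
tier0: PII
tier1: Identifiers
tier2: BiometricID

[OtherID]
locator: IDNUM
tier0: PII
tier1: Identifiers
tier2: OtherID
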