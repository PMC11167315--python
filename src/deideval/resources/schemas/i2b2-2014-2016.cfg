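# Shared schema for the 2014 and 2016 shared-task corpora (their category
# inventories were aligned): 28 native categories. Phone and Fax share the
# "PhoneFax" tier-1 scoring value in this configuration; Email and URL keep
# the broader ContactInformation group.

schema: i2b2-2014-2016
dialect: inline_xml

[Patient]
locator: PATIENT
tier0: PII
tier1: Names
tier2: Patient

[Doctor]
locator: DOCTOR
tier0: PII
tier1: Names
tier2: Provider

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

[Department]
locator: DEPARTMENT
tier0: PII
tier1: Address
tier2: Hospital

[Room]
locator: ROOM
tier0: PII
tier1: Address
tier2: OtherGeo

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

[LocationOther]
locator: LOCATION-OTHER
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
tier1: PhoneFax
tier2: Phone

[Fax]
locator: FAX
tier0: PII
tier1: PhoneFax
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

[IPAddress]
locator: IPADDRESS
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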