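# 2006 discharge-summary shared-task schema: eight native categories.
# The native "Location" category is the whole of the Address group for this
# corpus, "Medical Record" numbers are its only Identifiers, and "Age"
# covers only the strict HIPAA notion of ages over 89 years.

schema: i2b2-2006
dialect: inline_xml

[Location]
locator: LOCATION
tier0: PII
tier1: Address
tier2: OtherGeo

[Hospital]
locator: HOSPITAL
tier0: PII
tier1: Address
tier2: Hospital

[Phone]
locator: PHONE
tier0: PII
tier1: ContactInformation
tier2: Phone

[Doctor]
locator: DOCTOR
tier0: PII
tier1: Names
tier2: Provider

[Patient]
locator: PATIENT
tier0: PII
tier1: Names
tier2: Patient

[MedicalRecord]
locator: ID
tier0: PII
tier1: Identifiers
tier2: MedicalRecord

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
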