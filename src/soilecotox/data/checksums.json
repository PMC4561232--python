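{
 "enzyme_activity.csv": "0d026dba62a32d31f408aa3849c2ad39a6d4ca5971e0181dd793f4bc406194c5",
 "enzyme_activity_summary.csv": "fddb0f567fa433dc6ff96330033458b87df03427f6a519df0219b9c5d3f613df",
 "microbial_counts.csv": "e5e1002014e0ba4886aaf814331c696b768b529475879e14a9e133c1fa95e187",
 "microbial_counts_summary.csv": "ad9839b7e38b4fe9f9084ab1029cea4f7e8cef44cc73d7a2a8229a279c7fb7fd",
 "pec.csv": "aa88026e910161647ab7d510b4c7f8c88df8f1f1b450cc80f9d1c8b774dce9bd",
 "resilience.csv": "101831a2b0c0c37b40dffe65afcb726f75220370eabdcf6208e77f348f88e1d1",
 "resilience_summary.csv": "7be11384197a1c092b37ccb440a318c2322d3c5fcfd4dffa7385ecb988ef63cf",
 "resistance.csv": "8c82c702241f172c265ef5111c07c02f1b0678bfe34877e1b2a6e774a936aa4e",
 "resistance_summary.csv": "7e6f7147b708fe5f6fe3d64d02e57670df5e39dd5ff947bc2abaf330573c25ca",
 "soil_metadata.csv": "996441001cdc492d8f26e1650029a16efcce0f216c05b35614b1b90051bd8cb4"
}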