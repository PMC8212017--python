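ndc,atc
00002751001,A10A
00002821501,A10B
00088222033,A10A
00075062410,B01AB
00056017075,B01AC
00008084199,B01AA
00078043515,C02AC
00006074931,C02DB
00065432101,C03CA
00054829711,C03DA
00087606442,C09AA
00006001431,C09CA
00071015523,C10AA
00006074054,C10AA
00025152531,M01AE
00045044010,M01AB
00270044501,V08AB
00407141005,V08AA
00019975402,V08AB
00093102001,C03CA
00093102001,C09AA
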