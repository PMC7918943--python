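symbol	chrom	strand	start	end	role	exons
RB1	13	+	48877887	49056122	TSG	48877887-48878171;48884726-48885010;48891566-48891780;48898406-48898740;48905246-48905505;48912086-48912325;48918925-48919145;48925765-48925931;48932605-48932848;48939445-48939694;48946285-48946522;48953124-48953213;48959964-48960116;48966804-48966952;48973644-48973928;48980484-48980694;48987323-48987418;48994163-48994324;49001003-49001338;49007843-49008117;49014683-49014848;49021522-49021853;49028362-49028500;49035202-49035527;49042042-49042162;49048882-49048984;49055722-49055815
MYCN	2	+	16080683	16087129	oncogene	16080683-16080835;16083706-16083930;16086729-16087071
MDM4	1	+	204485507	204542871	oncogene	204485507-204485741;204491203-204491353;204496899-204497016;204502596-204502892;204508292-204508604;204513989-204514284;204519685-204520011;204525381-204525634;204531078-204531229;204536774-204537034;204542471-204542767
BCOR	X	-	39909068	40036582	TSG	39909068-39909211;39918147-39918494;39927227-39927312;39936306-39936497;39945386-39945500;39954465-39954807;39963545-39963658;39972625-39972792;39981704-39981906;39990784-39990947;39999863-40000071;40008943-40009069;40018022-40018282;40027102-40027240;40036182-40036478
CREBBP	16	-	3775055	3930121	TSG	3775055-3775202;3780210-3780403;3785366-3785621;3790521-3790631;3795677-3796010;3800832-3800981;3805988-3806231;3811143-3811355;3816299-3816501;3821454-3821557;3826610-3826919;3831765-3832038;3836921-3837098;3842076-3842245;3847232-3847420;3852388-3852632;3857543-3857628;3862699-3862940;3867854-3867972;3873010-3873312;3878165-3878320;3883321-3883640;3888476-3888767;3893632-3893941;3898787-3898977;3903943-3904165;3909098-3909363;3914254-3914458;3919409-3919615;3924565-3924651;3929721-3929891
EXT2	11	+	44117099	44271921	TSG	44117099-44117431;44127393-44127595;44137688-44137858;44147983-44148256;44158278-44158393;44168573-44168703;44178867-44179000;44189162-44189373;44199457-44199634;44209752-44210070;44220047-44220190;44230341-44230479;44240636-44240757;44250931-44251088;44261226-44261421;44271521-44271693
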