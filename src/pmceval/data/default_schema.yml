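# Default evaluation framework for Chinese medicine new-drug registration
# policies: nine primary variables, 41 binary sub-variables, equal weights.
name: TCM registration policy evaluation framework
primaries:
  - id: X1
    label: Nature of policy
    subvariables:
      - {id: X1_1, label: Forecast, criterion: Determine if the policy reflects the forecast}
      - {id: X1_2, label: Guidance, criterion: Determine if the policy reflects guidance}
      - {id: X1_3, label: Description, criterion: Determine if the policy reflects the description}
      - {id: X1_4, label: Regulation, criterion: Determine if the policy reflects regulation}
      - {id: X1_5, label: Plan, criterion: Determine if the policy reflects the plan}
      - {id: X1_6, label: Support, criterion: Determine if the policy reflects support}
  - id: X2
    label: Policy timeliness
    subvariables:
      - {id: X2_1, label: Long term (3-5 years), criterion: Determine if the policy is a long-term policy}
      - {id: X2_2, label: Short term (1-3 years), criterion: Determine if the policy is a short-term policy}
      - {id: X2_3, label: Within one year, criterion: Determine if the policy is a one-year limitation policy}
  - id: X3
    label: Issuing institution
    subvariables:
      - {id: X3_1, label: Country, criterion: Determine if the policy is issued by a state agency}
      - {id: X3_2, label: Autonomous regions and municipalities, criterion: Determine whether the policy is issued by an autonomous region and municipality}
      - {id: X3_3, label: Administrative departments, criterion: Determine if the policy is issued by each executive branch}
      - {id: X3_4, label: Other, criterion: Determine if the policy is issued for other agencies}
  - id: X4
    label: Object of policy
    subvariables:
      - {id: X4_1, label: Authority, criterion: Determine if the target of the policy is an authority}
      - {id: X4_2, label: Business, criterion: Determine if the policy is aimed at a business}
      - {id: X4_3, label: Hospital, criterion: Determine if the policy is targeted to a hospital}
      - {id: X4_4, label: Laboratory, criterion: Determine if the subject of the policy is a laboratory}
  - id: X5
    label: Policy function
    subvariables:
      - {id: X5_1, label: Guiding development, criterion: Determine if the policy function has guided development}
      - {id: X5_2, label: Prescriptive standards, criterion: Determine if the policy function has a prescribed standard}
      - {id: X5_3, label: Optimization procedure, criterion: Determine if the policy function has an optimization procedure}
      - {id: X5_4, label: Encourage innovation, criterion: Determine whether the policy function is encouraging innovation}
      - {id: X5_5, label: Optimize product structure, criterion: Determine if the policy function has an optimized product structure}
      - {id: X5_6, label: Perfect the system, criterion: Determine if the policy function has a perfect system}
  - id: X6
    label: Policy content
    subvariables:
      - {id: X6_1, label: Technical guidance, criterion: Determine if the policy content has technical guidance}
      - {id: X6_2, label: Prioritizing resources, criterion: Determine if the policy content has a priority allocation resource}
      - {id: X6_3, label: Shorten review time limit, criterion: Determine if the policy content has a shortened review time limit}
      - {id: X6_4, label: Application requirements, criterion: Determine if the policy content is eligible for application}
      - {id: X6_5, label: Application path, criterion: Determine if the policy content has an application path}
      - {id: X6_6, label: Registration verification and inspection, criterion: Determine if the policy content has registration verification and inspection}
  - id: X7
    label: Policy approach
    subvariables:
      - {id: X7_1, label: Coercive, criterion: Determine if the policy approach is coercive}
      - {id: X7_2, label: Service type, criterion: Determine if the policy approach is service-oriented}
      - {id: X7_3, label: Incentive-based, criterion: Determine if the policy approach is incentive}
  - id: X8
    label: Incentive method
    subvariables:
      - {id: X8_1, label: Program simplification, criterion: Determine if the policy incentive method has procedural simplification}
      - {id: X8_2, label: Enrollment subsidy, criterion: Determine if the policy incentive method has an enrollment subsidy}
      - {id: X8_3, label: Intellectual property protection, criterion: Determine whether the policy incentive method has intellectual property protection}
      - {id: X8_4, label: Regulation and evaluation, criterion: Determine whether the policy incentive method has regulation and evaluation}
  - id: X9
    label: Scientificity of policy
    subvariables:
      - {id: X9_1, label: Well-founded, criterion: Determine whether the policy is scientifically sound}
      - {id: X9_2, label: Detailed content, criterion: Determine whether the policy is scientific and detailed}
      - {id: X9_3, label: Detail measures, criterion: Determine whether the policy is scientific and refined measures}
      - {id: X9_4, label: Clear division of labor, criterion: Determine whether the scientific nature of the policy has a clear division of labor}
      - {id: X9_5, label: Clear responsibilities and rights, criterion: Determine whether the scientific nature of the policy is clear in terms of responsibilities and rights}
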